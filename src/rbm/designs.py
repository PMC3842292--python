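"""Design matrices for two-colour microarray layouts and two-group comparisons.

Two-colour arrays hybridise two samples per slide, one labelled with Cy3
(green) and one with Cy5 (red); the measured quantity per gene is the log2
ratio red/green.  The classic layouts (direct comparison, dye swap, common
reference, loop) are encoded here as +/-1 contrasts of per-sample effects,
with the convention that a treatment on the red channel contributes
positively to the tested effect.  Single-channel two-group comparisons use
an (intercept, group-indicator) parameterisation so that the tested
coefficient is directly the group mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DesignError",
    "RankDeficientError",
    "AmbiguousContrastError",
    "DesignSpec",
    "DesignMatrix",
    "build_design",
    "contrast_of_interest",
]

TWO_COLOR_KINDS = ("two_color_a", "two_color_b", "two_color_c", "two_color_d")
KINDS = TWO_COLOR_KINDS + ("two_group",)

# Numerical tolerance for the full-column-rank check.
_RANK_RTOL = 1e-10


class DesignError(ValueError):
    """Invalid design specification."""


class RankDeficientError(DesignError):
    """Design matrix is not of full column rank."""


class AmbiguousContrastError(DesignError):
    """The treatment-vs-control contrast cannot be inferred automatically."""


@dataclass(frozen=True)
class DesignSpec:
    """Specification of an experimental layout.

    Parameters
    ----------
    kind:
        One of ``two_color_a`` (direct comparison), ``two_color_b``
        (dye swap), ``two_color_c`` (common reference), ``two_color_d``
        (loop / direct design), or ``two_group`` (single-channel).
    arrays:
        For two-colour kinds, one ``(green, red)`` sample-name pair per
        array (green = Cy3, red = Cy5).  For ``two_group``, one group
        label per array.
    baseline:
        Sample treated as the reference level (its effect is absorbed).
        Defaults to the common reference for design (c), otherwise to the
        green sample of the first array; for ``two_group``, to the
        first-seen group label.
    """

    kind: str
    arrays: tuple
    baseline: str | None = None

    def __init__(self, kind: str, arrays: Sequence, baseline: str | None = None):
        if kind not in KINDS:
            raise DesignError(f"unknown design kind {kind!r}; expected one of {KINDS}")
        arrays = tuple(tuple(a) if isinstance(a, (tuple, list)) else a for a in arrays)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "arrays", arrays)
        object.__setattr__(self, "baseline", baseline)
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        n = len(self.arrays)
        if self.kind == "two_group":
            if n < 2:
                raise DesignError("two_group design needs at least 2 arrays")
            labels = set(self.arrays)
            if len(labels) != 2:
                raise DesignError(
                    f"two_group design needs exactly 2 distinct group labels, got {sorted(map(str, labels))}"
                )
            return
        # two-colour kinds: every array is a (green, red) pair of distinct samples
        for a in self.arrays:
            if not (isinstance(a, tuple) and len(a) == 2):
                raise DesignError(f"two-colour array descriptor must be a (green, red) pair, got {a!r}")
            if a[0] == a[1]:
                raise DesignError(f"array hybridises sample {a[0]!r} against itself")
        if self.kind == "two_color_a":
            if n < 1:
                raise DesignError("direct-comparison design needs at least 1 array")
            if len(set(self.arrays)) != 1:
                raise DesignError("design (a) replicates the same (green, red) hybridisation on every array")
        elif self.kind == "two_color_b":
            if n != 2:
                raise DesignError(f"dye-swap design has exactly 2 arrays, got {n}")
            (g1, r1), (g2, r2) = self.arrays
            if (g1, r1) != (r2, g2):
                raise DesignError("dye-swap arrays must hybridise the same pair with dyes exchanged")
        elif self.kind == "two_color_c":
            if n < 2:
                raise DesignError(f"common-reference design needs at least 2 arrays, got {n}")
            if not self._common_samples():
                raise DesignError("common-reference design requires one sample present on every array")
        elif self.kind == "two_color_d":
            if n < 2:
                raise DesignError(f"loop design needs at least 2 arrays, got {n}")

    def _common_samples(self) -> set:
        common = set(self.arrays[0])
        for a in self.arrays[1:]:
            common &= set(a)
        return common

    # -- helpers ------------------------------------------------------

    def reference(self) -> str:
        """The sample (or group label) absorbed as the baseline."""
        if self.baseline is not None:
            return self.baseline
        if self.kind == "two_group":
            return self.arrays[0]
        if self.kind == "two_color_c":
            # prefer the shared reference; if several (2 arrays), the shared green one
            common = sorted(self._common_samples(), key=lambda s: [a[0] for a in self.arrays].count(s), reverse=True)
            return common[0]
        return self.arrays[0][0]


@dataclass(frozen=True)
class DesignMatrix:
    """A full-column-rank design matrix with named coefficients."""

    X: np.ndarray
    coef_names: tuple

    def __init__(self, X: np.ndarray, coef_names: Sequence[str]):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DesignError("design matrix must be 2-dimensional")
        if X.shape[1] != len(coef_names):
            raise DesignError("number of coefficient names must match columns")
        _check_full_rank(X, tuple(coef_names))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "coef_names", tuple(coef_names))

    @property
    def n_arrays(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def _check_full_rank(X: np.ndarray, names: tuple) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficientError(
            f"more coefficients ({X.shape[1]}) than arrays ({X.shape[0]})"
        )
    # QR with column pivoting: a tiny trailing R diagonal names the redundant column
    _, r, piv = _qr_pivot(X)
    diag = np.abs(np.diag(r))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    bad = np.where(diag <= _RANK_RTOL * scale)[0]
    if bad.size:
        raise RankDeficientError(
            f"design is rank deficient: column {names[piv[bad[0]]]!r} is redundant"
        )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def build_design(spec: DesignSpec) -> DesignMatrix:
    """Construct the design matrix for a layout specification.

    Two-colour arrays are encoded as contrasts of per-sample effects with
    the reference sample absorbed: the row for an array with samples
    ``(green, red)`` carries +1 in the red sample's column and -1 in the
    green sample's column (log2 red/green convention).  ``two_group``
    produces an intercept plus a group indicator, so the second
    coefficient is the between-group mean difference.
    """
    if spec.kind == "two_group":
        ref = spec.reference()
        other = next(g for g in spec.arrays if g != ref)
        ind = np.array([0.0 if g == ref else 1.0 for g in spec.arrays])
        X = np.column_stack([np.ones(len(spec.arrays)), ind])
        return DesignMatrix(X, ("intercept", f"{other}-{ref}"))

    ref = spec.reference()
    samples = []
    for g, r in spec.arrays:
        for s in (g, r):
            if s != ref and s not in samples:
                samples.append(s)
    X = np.zeros((len(spec.arrays), len(samples)))
    col = {s: j for j, s in enumerate(samples)}
    for i, (g, r) in enumerate(spec.arrays):
        if r != ref:
            X[i, col[r]] += 1.0
        if g != ref:
            X[i, col[g]] -= 1.0
    return DesignMatrix(X, tuple(samples))


def contrast_of_interest(design: DesignMatrix) -> int:
    """Index of the coefficient whose null ``beta = 0`` is tested.

    Single-coefficient designs test their only column.  Two-group designs
    test the group-difference column.  Multi-sample two-colour designs
    test the column named ``"T"`` when present; otherwise the choice is
    ambiguous and must be made explicitly by the caller.
    """
    if design.n_coef == 1:
        return 0
    for j, name in enumerate(design.coef_names):
        if name == "T" or (("-" in name) and name != "intercept" and "intercept" in design.coef_names):
            return j
    raise AmbiguousContrastError(
        f"cannot infer the treatment-vs-control column among {design.coef_names}; "
        "select the coefficient index explicitly"
    )
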