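"""Manhattan covariate distance matrices and (partial) Mantel tests.

Distance-matrix entries are not independent, so correlations between a
compositional dissimilarity matrix and an environmental distance matrix
are tested by jointly permuting rows and columns of one matrix.  The
partial test residualises both upper-triangle vectors on the controlling
distance matrices (method of residuals) before correlating, and permutes
the raw response matrix with re-residualisation at every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .beta import DissimilarityMatrix
from .errors import ValidationError, ZeroVarianceError


@dataclass(frozen=True)
class MantelResult:
    """Correlation r, permutation p, and test metadata."""

    r: float
    p: float
    n_perm: int
    mode: str                      # "simple" or "partial"
    controlled: tuple = ()
    alternative: str = "two-sided"


def manhattan_matrix(values, labels: Sequence[str]) -> DissimilarityMatrix:
    """|v_i - v_j| distance matrix of one covariate."""
    v = np.asarray(values, dtype=float)
    if v.size != len(labels):
        raise ValidationError("values and labels differ in length")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite covariate values")
    if v.size < 2:
        raise ValidationError("need at least two squares")
    d = np.abs(v[:, None] - v[None, :])
    return DissimilarityMatrix(list(labels), d, "manhattan")


def _check_aligned(mats: Sequence[DissimilarityMatrix]) -> None:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValidationError("distance matrices have different labels/order")


def _pair_mask(mats: Sequence[DissimilarityMatrix], n: int) -> np.ndarray:
    """Upper-triangle positions valid in every matrix (listwise deletion)."""
    iu = np.triu_indices(n, 1)
    mask = np.ones(iu[0].size, dtype=bool)
    for m in mats:
        vec = m.values[iu]
        mask &= np.isfinite(vec)
        if m.missing is not None:
            mask &= ~m.missing[iu]
    return mask


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ZeroVarianceError("zero variance in a distance vector")
    return float((xc @ yc) / denom)


def _p_value(r_obs: float, r_perm: np.ndarray, alternative: str) -> float:
    eps = 1e-12
    if alternative == "two-sided":
        exceed = np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - eps)
    elif alternative == "greater":
        exceed = np.count_nonzero(r_perm >= r_obs - eps)
    elif alternative == "less":
        exceed = np.count_nonzero(r_perm <= r_obs + eps)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (exceed + 1) / (r_perm.size + 1)


def mantel(
    A: DissimilarityMatrix,
    B: DissimilarityMatrix,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Simple Mantel test between two distance matrices.

    r is the Pearson correlation of the strictly-upper-triangle vectors;
    p comes from joint row/column permutations of A with the add-one
    correction, two-sided on |r| by default.
    """
    _check_aligned([A, B])
    n = A.n
    iu = np.triu_indices(n, 1)
    mask = _pair_mask([A, B], n)
    if not mask.any():
        raise ZeroVarianceError("no valid square pairs")
    bu = B.values[iu][mask]
    r_obs = _pearson(A.values[iu][mask], bu)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        av = A.values[np.ix_(p, p)][iu][mask]
        r_perm[k] = _pearson(av, bu)
    return MantelResult(
        r=r_obs, p=_p_value(r_obs, r_perm, alternative),
        n_perm=n_perm, mode="simple", alternative=alternative,
    )


def partial_mantel(
    A: DissimilarityMatrix,
    B: DissimilarityMatrix,
    C: Sequence[DissimilarityMatrix],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    alternative: str = "two-sided",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for the matrices in C.

    Both upper-triangle vectors are residualised by OLS on the control
    vectors (with intercept); r is the Pearson correlation of residuals.
    Permutations shuffle the raw A matrix jointly over rows/columns and
    re-residualise before correlating.  With C empty this reduces exactly
    to the simple test.
    """
    C = list(C)
    if not C:
        res = mantel(A, B, n_perm=n_perm, seed=seed, alternative=alternative)
        return MantelResult(res.r, res.p, res.n_perm, "partial", (), alternative)
    _check_aligned([A, B, *C])
    n = A.n
    iu = np.triu_indices(n, 1)
    mask = _pair_mask([A, B, *C], n)
    if not mask.any():
        raise ZeroVarianceError("no valid square pairs")
    design = np.column_stack(
        [np.ones(int(mask.sum()))] + [c.values[iu][mask] for c in C]
    )
    q, _ = np.linalg.qr(design)

    def residualise(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    rb = residualise(B.values[iu][mask])
    if np.allclose(rb, 0.0, atol=1e-10 * max(1.0, float(np.abs(B.values[iu][mask]).max()))):
        raise ZeroVarianceError("B is collinear with the control matrices")
    ra = residualise(A.values[iu][mask])
    r_obs = _pearson(ra, rb)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        av = A.values[np.ix_(p, p)][iu][mask]
        r_perm[k] = _pearson(residualise(av), rb)
    names = tuple(getattr(c, "kind", "control") for c in C)
    return MantelResult(
        r=r_obs, p=_p_value(r_obs, r_perm, alternative),
        n_perm=n_perm, mode="partial", controlled=names, alternative=alternative,
    )
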