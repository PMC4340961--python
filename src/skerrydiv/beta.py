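"""Pairwise compositional dissimilarity between survey squares.

Two presence-absence indices:

* Sorensen dissimilarity  beta_S = 1 - 2w / (a + b), where a and b are the
  species counts of the two squares and w the shared count.  beta_S
  conflates richness differences with genuine turnover.
* Raup-Crick dissimilarity beta_RC, a null-model index: the probability of
  observing fewer shared species than expected when both squares are
  re-assembled by random draws from the regional pool, weighted by each
  species' regional occupancy, conditional on the two observed richness
  values.  High beta_RC means the squares share fewer species than chance
  predicts given their richness, i.e. richness-corrected turnover.

The Monte-Carlo null uses sequential weighted sampling without
replacement, realised through the exponential-key construction (the n
smallest of Exp(1)/w_s keys form exactly the same distribution over
species sets as draw-remove-renormalise sampling).  An exact enumeration
of the same null is provided for small pools as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import UndefinedPairError, ValidationError
from .io import SurveyDataset


@dataclass(frozen=True)
class PairwiseComposition:
    """Species counts of a square pair: a, b totals and w shared."""

    a: int
    b: int
    w: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.w) < 0 or self.w > min(self.a, self.b):
            raise ValidationError(
                f"invalid composition a={self.a}, b={self.b}, w={self.w}"
            )


@dataclass
class DissimilarityMatrix:
    """Symmetric square-by-square dissimilarity with optional missing pairs.

    ``kind`` is one of {"sorensen", "raup_crick", "manhattan"}.  Missing
    entries (e.g. Sorensen on two empty squares) carry NaN values and are
    flagged in ``missing``; downstream tests drop them listwise.
    """

    labels: list[str]
    values: np.ndarray
    kind: str
    missing: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("dissimilarity matrix shape/labels mismatch")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValidationError("dissimilarity matrix not symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle vector (NaN for missing pairs)."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def sorensen(p: PairwiseComposition) -> float:
    """Sorensen dissimilarity 1 - 2w/(a+b) of one square pair."""
    if p.a + p.b == 0:
        raise UndefinedPairError("Sorensen undefined for two empty squares")
    return 1.0 - 2.0 * p.w / (p.a + p.b)


@dataclass
class PoolWeights:
    """Regional-pool sampling weights: each species' occupied-square count."""

    species: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValidationError("pool weights must be non-negative")
        self.weights = w

    @property
    def gamma(self) -> int:
        """Pool size: number of species with positive weight."""
        return int(np.count_nonzero(self.weights > 0))

    def positive(self) -> np.ndarray:
        return self.weights[self.weights > 0]

    @classmethod
    def from_dataset(cls, ds: SurveyDataset, group: str = "all") -> "PoolWeights":
        sp = ds.occ.group_species(group)
        counts = ds.occ.presence[sp].sum(axis=0).to_numpy(dtype=float)
        return cls(species=sp, weights=counts)


@dataclass
class RaupCrickConfig:
    """Null-model settings: draws per unique richness pair and seed.

    Ties between null and observed shared counts carry half weight, which
    keeps the index centred on 0.5 under the null.  ``rescale_minus1_1``
    maps [0, 1] onto [-1, 1] (2x - 1) when set.
    """

    reps: int = 999
    seed: Optional[int] = None
    rescale_minus1_1: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")


def _draw_membership(
    rng: np.random.Generator, weights: np.ndarray, n: int, reps: int
) -> np.ndarray:
    """reps independent draws of n distinct species, sequential-weighted.

    Exponential-key trick: taking the n smallest of Exp(1)/w_s keys is
    distributionally identical to drawing species one at a time with
    probability proportional to weight among those remaining.
    """
    s = weights.size
    memb = np.zeros((reps, s), dtype=bool)
    if n == 0:
        return memb
    if n > s:
        raise ValidationError(f"cannot draw {n} species from a pool of {s}")
    keys = rng.standard_exponential((reps, s)) / weights
    idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    np.put_along_axis(memb, idx, True, axis=1)
    return memb


def _null_shared(
    rng: np.random.Generator, weights: np.ndarray, n1: int, n2: int, reps: int
) -> np.ndarray:
    a = _draw_membership(rng, weights, n1, reps)
    b = _draw_membership(rng, weights, n2, reps)
    return (a & b).sum(axis=1)


def _beta_rc_from_null(w_null: np.ndarray, w_obs: int, rescale: bool = False) -> float:
    """Half-tie survival probability of the observed shared count."""
    reps = w_null.size
    v = (np.count_nonzero(w_null > w_obs) + 0.5 * np.count_nonzero(w_null == w_obs)) / reps
    return 2.0 * v - 1.0 if rescale else v


def raup_crick_pair(
    n1: int, n2: int, w_obs: int, pool: PoolWeights, cfg: RaupCrickConfig
) -> float:
    """Monte-Carlo beta_RC for one square pair.

    High values mean the pair shares fewer species than the richness-
    conditioned weighted null expects.
    """
    w = pool.positive()
    if max(n1, n2) > w.size:
        raise ValidationError(
            f"richness ({n1},{n2}) exceeds positive-weight pool size {w.size}"
        )
    if w_obs > min(n1, n2):
        raise ValidationError("shared count exceeds the smaller richness")
    rng = np.random.default_rng(cfg.seed)
    w_null = _null_shared(rng, w, n1, n2, cfg.reps)
    return _beta_rc_from_null(w_null, w_obs, cfg.rescale_minus1_1)


def _exact_set_probs(weights: np.ndarray, n: int) -> dict[frozenset, float]:
    """Probability of each species set of size n under sequential draws."""
    s = weights.size
    total = float(weights.sum())
    out: dict[frozenset, float] = {}
    for comb in combinations(range(s), n):
        p = 0.0
        for perm in permutations(comb):
            q, rem = 1.0, total
            for i in perm:
                q *= weights[i] / rem
                rem -= weights[i]
            p += q
        out[frozenset(comb)] = p
    return out


def exact_shared_pmf(n1: int, n2: int, weights) -> np.ndarray:
    """Exact pmf of the null shared-species count for a small pool.

    Enumerates every ordered outcome of the sequential weighted draws for
    both squares; feasible for pools of <= ~6 species and richness <= ~3.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if max(n1, n2) > w.size:
        raise ValidationError("richness exceeds positive-weight pool size")
    p1 = _exact_set_probs(w, n1)
    p2 = _exact_set_probs(w, n2)
    pmf = np.zeros(min(n1, n2) + 1)
    for s1, q1 in p1.items():
        for s2, q2 in p2.items():
            pmf[len(s1 & s2)] += q1 * q2
    return pmf


def raup_crick_exact(
    n1: int, n2: int, w_obs: int, weights, rescale: bool = False
) -> float:
    """Exact beta_RC by enumeration of the sequential-draw null."""
    pmf = exact_shared_pmf(n1, n2, weights)
    shared = np.arange(pmf.size)
    v = pmf[shared > w_obs].sum() + 0.5 * pmf[shared == w_obs].sum() if w_obs < pmf.size else 0.0
    return 2.0 * v - 1.0 if rescale else float(v)


class SorensenDissimilarity(TransformerMixin, BaseEstimator):
    """Transformer computing the pairwise Sorensen dissimilarity matrix.

    ``transform`` accepts a squares x species 0/1 array or DataFrame and
    returns a :class:`DissimilarityMatrix`.  Pairs where both squares are
    empty are flagged missing (NaN) rather than raising.
    """

    def fit(self, X, y=None):
        X = self._validate_presence(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> DissimilarityMatrix:
        labels = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(X))]
        P = self._validate_presence(X)
        r = P.sum(axis=1)
        shared = P @ P.T
        denom = r[:, None] + r[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 1.0 - 2.0 * shared / denom
        missing = denom == 0
        vals[missing] = np.nan
        np.fill_diagonal(vals, 0.0)
        np.fill_diagonal(missing, False)
        return DissimilarityMatrix(labels, vals, "sorensen", missing)

    def fit_transform(self, X, y=None, **kw) -> DissimilarityMatrix:
        return self.fit(X).transform(X)

    @staticmethod
    def _validate_presence(X) -> np.ndarray:
        P = np.asarray(X, dtype=float)
        if P.ndim != 2:
            raise ValidationError("presence matrix must be 2-D")
        if not np.isin(P, (0.0, 1.0)).all():
            raise ValidationError("presence matrix entries must be 0/1")
        return P


class RaupCrickDissimilarity(TransformerMixin, BaseEstimator):
    """Transformer computing the pairwise Raup-Crick null-model matrix.

    ``fit`` learns the regional pool weights (per-species occupied-square
    counts) from the supplied presence matrix; ``transform`` evaluates
    beta_RC for every square pair of its input against that pool.  The
    null distribution of shared species depends only on the two richness
    values, so it is simulated once per unique richness pair and cached
    (``null_cache_``), which is what makes thousands of squares feasible.

    Parameters
    ----------
    reps : draws per unique richness pair (default 999).
    random_state : seed for the null draws.
    rescale_minus1_1 : emit the 2x-1 rescaling onto [-1, 1].
    """

    def __init__(self, reps: int = 999, random_state: Optional[int] = None,
                 rescale_minus1_1: bool = False):
        self.reps = reps
        self.random_state = random_state
        self.rescale_minus1_1 = rescale_minus1_1

    def fit(self, X, y=None):
        P = SorensenDissimilarity._validate_presence(X)
        self.pool_weights_ = P.sum(axis=0)
        self.n_features_in_ = P.shape[1]
        return self

    def transform(self, X) -> DissimilarityMatrix:
        if not hasattr(self, "pool_weights_"):
            raise ValidationError("RaupCrickDissimilarity is not fitted")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        labels = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(X))]
        P = SorensenDissimilarity._validate_presence(X)
        if P.shape[1] != self.n_features_in_:
            raise ValidationError("species axis differs between fit and transform")
        w = self.pool_weights_[self.pool_weights_ > 0]
        r = P.sum(axis=1).astype(int)
        if r.max(initial=0) > w.size:
            raise ValidationError(
                "a square's richness exceeds the positive-weight pool size"
            )
        rng = np.random.default_rng(self.random_state)
        # simulate the null once per unique unordered richness pair,
        # in sorted order so results are seed-deterministic
        pairs = sorted({tuple(sorted((r[i], r[j])))
                        for i in range(len(r)) for j in range(i + 1, len(r))})
        self.null_cache_ = {
            p: _null_shared(rng, w, p[0], p[1], self.reps) for p in pairs
        }
        shared = (P @ P.T).astype(int)
        n = len(r)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((r[i], r[j])))
                v = _beta_rc_from_null(self.null_cache_[key], shared[i, j],
                                       self.rescale_minus1_1)
                vals[i, j] = vals[j, i] = v
        return DissimilarityMatrix(labels, vals, "raup_crick")

    def fit_transform(self, X, y=None, **kw) -> DissimilarityMatrix:
        return self.fit(X).transform(X)


def sorensen_matrix(ds: SurveyDataset, group: str = "all") -> DissimilarityMatrix:
    """Sorensen dissimilarity between all square pairs for one species group."""
    sp = ds.occ.group_species(group)
    return SorensenDissimilarity().fit_transform(ds.occ.presence[sp])


def raup_crick_matrix(
    ds: SurveyDataset, group: str = "all", cfg: Optional[RaupCrickConfig] = None
) -> DissimilarityMatrix:
    """Raup-Crick dissimilarity for one species group.

    Pool weights are the group species' occupied-square counts over the
    full regional dataset (group-specific pool).
    """
    cfg = cfg or RaupCrickConfig()
    sp = ds.occ.group_species(group)
    est = RaupCrickDissimilarity(
        reps=cfg.reps, random_state=cfg.seed,
        rescale_minus1_1=cfg.rescale_minus1_1,
    )
    return est.fit_transform(ds.occ.presence[sp])
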