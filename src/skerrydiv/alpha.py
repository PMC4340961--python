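"""Per-square species richness, occupancy summaries, covariate
standardisation, and gradient binning.

Alpha diversity here is plain richness: the number of species recorded
in a square, split by habitat group (coastal specialist vs. generalist)
and red-list status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ZeroVarianceError
from .io import SurveyDataset

RICHNESS_COLUMNS = [
    "total", "specialist", "generalist",
    "redlist_total", "redlist_specialist", "redlist_generalist",
]

#: Map from richness column to the species-group label used elsewhere.
RESPONSE_GROUPS = {
    "total": "all",
    "specialist": "specialist",
    "generalist": "generalist",
    "redlist_total": "redlist_all",
    "redlist_specialist": "redlist_specialist",
    "redlist_generalist": "redlist_generalist",
}


def richness(ds: SurveyDataset) -> pd.DataFrame:
    """Species counts per square and group.

    Returns a DataFrame indexed by square id with the six columns in
    RICHNESS_COLUMNS.  specialist + generalist = total and the red-list
    columns satisfy the same partition by construction.
    """
    occ = ds.occ
    out = {}
    for col, group in RESPONSE_GROUPS.items():
        sp = occ.group_species(group)
        out[col] = occ.presence[sp].sum(axis=1).astype(int)
    return pd.DataFrame(out, index=occ.presence.index)


def occupancy_table(ds: SurveyDataset) -> pd.DataFrame:
    """Per-species occurrence counts and percent of occupied squares.

    Percentages are 100 * count / n_squares rounded to one decimal,
    the resolution at which survey occupancy tables are reported.
    """
    occ = ds.occ
    n = len(occ.squares)
    if n < 1:
        raise ZeroVarianceError("occupancy requires at least one square")
    counts = occ.presence.sum(axis=0).astype(int)
    tf = occ.trait_frame()
    out = pd.DataFrame(
        {
            "occurrences": counts,
            "proportion_pct": np.round(100.0 * counts / n, 1),
            "classification": tf["classification"],
            "redlist": tf["redlist"],
        }
    )
    out.index.name = "species"
    return out.sort_index()


@dataclass(frozen=True)
class Standardisation:
    """A fitted centre-and-scale transform (z-score by default)."""

    values: np.ndarray
    mean: float
    scale: float

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * self.scale + self.mean


def standardise(values, method: str = "zscore") -> Standardisation:
    """Mean-standardise a covariate vector.

    ``zscore`` (default) centres and scales to unit sample SD; ``center``
    only subtracts the mean.  Raises ZeroVarianceError on constant input.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ZeroVarianceError("standardise needs at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("cannot standardise a constant vector")
    if method == "zscore":
        return Standardisation((v - mean) / sd, mean, sd)
    if method == "center":
        return Standardisation(v - mean, mean, 1.0)
    raise ValueError(f"unknown standardisation method {method!r}")


def standardise_covariates(ds: SurveyDataset, method: str = "zscore") -> pd.DataFrame:
    """Standardised dist_sea / width / shoreline / land_area per square."""
    cov = ds.covariate_frame()
    return pd.DataFrame(
        {c: standardise(cov[c].to_numpy(), method).values for c in cov.columns},
        index=cov.index,
    )


def bin_by_gradient(
    rt: pd.DataFrame, z, half_width: float = 0.25
) -> pd.DataFrame:
    """Group squares into gradient bins and summarise richness per bin.

    Bins are centred at multiples of 2*half_width on the standardised
    gradient with half-open membership [centre - hw, centre + hw), ties
    going to the upper bin.  Returns one row per (bin centre, group) with
    n, mean and SD of richness.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    z = np.asarray(z, dtype=float)
    if z.shape[0] != len(rt):
        raise ValueError("gradient vector and richness table differ in length")
    centres = 2.0 * half_width * np.floor(z / (2.0 * half_width) + 0.5)
    rows = []
    for c in np.unique(centres):
        sel = rt.loc[centres == c]
        for col in rt.columns:
            rows.append(
                {
                    "bin_centre": float(c),
                    "group": col,
                    "n": int(len(sel)),
                    "mean_richness": float(sel[col].mean()),
                    "sd_richness": float(sel[col].std(ddof=1)) if len(sel) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
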