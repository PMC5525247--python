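"""Dyadic analysis table and grouped Spearman correlations.

Each focal mouse contributes four dyads (one per satellite cage). The
response is the square-root-transformed dwell duration in the satellite's
cage; the covariate of interest is MHCpat, the amino-acid p-distance
between the focal mouse's father and the satellite. Correlations are
reported per group — all mice; pure vs mixed population background; and
sex × paternal population background (xF/xG = father from population
F/G) — as Spearman's r with the t-approximation t = r·√((n−2)/(1−r²)),
df = n−2, and a two-sided p from the central t distribution.

Spearman is rank-based, so the square-root transform does not change r;
the transformed column is retained in the table for output fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gendist import Cohort, DyadicCovariates

MIN_GROUP_N = 5

#: output order of the grouped table
GROUP_ORDER = {
    "all": ["All mice"],
    "purity": ["Pure population background", "Mixed population background"],
    "sex_paternal": ["xF females", "xG females", "xF males", "xG males"],
}


@dataclass
class CorrelationResult:
    group: str
    r: float
    t: float
    df: int
    p: float
    n: int

    def defined(self) -> bool:
        return not math.isnan(self.r)


def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    NaN (undefined) when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return float("nan")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def t_from_r(r: float, n: int) -> tuple[float, int]:
    """t-statistic and df for a correlation coefficient: df = n−2,
    t = r·√(df/(1−r²)); |r| = 1 maps to ±inf."""
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r), df
    return r * math.sqrt(df / (1.0 - r * r)), df


def p_two_sided(t: float, df: int) -> float:
    """Two-sided tail probability of the central t distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


def correlate(x, y, group: str = "") -> CorrelationResult:
    """Full Spearman result (r, t, df, p, n) for one group of dyads."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    r = spearman_r(x, y)
    if math.isnan(r):
        return CorrelationResult(group, math.nan, math.nan, n - 2, math.nan, n)
    t, df = t_from_r(r, n)
    return CorrelationResult(group, r, t, df, p_two_sided(t, df), n)


# ---------------------------------------------------------------------------
# dyad table
# ---------------------------------------------------------------------------

def build_dyad_table(
    durations: dict[str, np.ndarray],
    covariates: dict[str, list[DyadicCovariates]],
    cohort: Cohort,
) -> pd.DataFrame:
    """Assemble the tidy dyad table: one row per (focal, satellite).

    ``durations`` maps focal id → four satellite dwell totals in hours
    (cage order = satellite order in ``covariates``). Rows whose MHCpat is
    missing are flagged ``excluded`` and skipped by the correlation stage;
    the exclusion count is stored in ``df.attrs['n_excluded']``.
    """
    rows = []
    for fid, dvec in durations.items():
        covs = covariates[fid]
        if len(covs) != 4 or len(dvec) != 4:
            raise ValueError(f"focal {fid!r} must have exactly 4 dyads")
        focal = cohort[fid]
        for k, cov in enumerate(covs):
            dur = float(dvec[k])
            rows.append(
                {
                    "focal_id": fid,
                    "satellite_id": cov.satellite_id,
                    "cage": k + 1,
                    "duration_h": dur,
                    "sqrt_duration": math.sqrt(dur),
                    "mhcpat": cov.mhcpat,
                    "mhcmat": cov.mhcmat,
                    "mhc": cov.mhc,
                    "mhc_diversity": cov.mhc_diversity,
                    "cas": cov.cas,
                    "casmat": cov.casmat,
                    "caspat": cov.caspat,
                    "dps": cov.dps,
                    "match_category": cov.match_category,
                    "focal_sex": focal.sex,
                    "paternal_group": f"x{focal.paternal_pop}",
                    "purity": "pure" if focal.pure else "mixed",
                    "excluded": bool(cov.missing_parent or math.isnan(cov.mhcpat)),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = int(df["excluded"].sum()) if len(df) else 0
    return df


def _group_masks(df: pd.DataFrame, grouping: str) -> dict[str, pd.Series]:
    if grouping == "all":
        return {"All mice": pd.Series(True, index=df.index)}
    if grouping == "purity":
        return {
            "Pure population background": df["purity"] == "pure",
            "Mixed population background": df["purity"] == "mixed",
        }
    if grouping == "sex_paternal":
        return {
            "xF females": (df["paternal_group"] == "xF") & (df["focal_sex"] == "F"),
            "xG females": (df["paternal_group"] == "xG") & (df["focal_sex"] == "F"),
            "xF males": (df["paternal_group"] == "xF") & (df["focal_sex"] == "M"),
            "xG males": (df["paternal_group"] == "xG") & (df["focal_sex"] == "M"),
        }
    raise ValueError(f"unknown grouping {grouping!r}")


def grouped_correlations(
    dyads: pd.DataFrame,
    grouping: str = "sex_paternal",
    covariate: str = "mhcpat",
    response: str = "sqrt_duration",
    min_n: int = MIN_GROUP_N,
) -> pd.DataFrame:
    """Spearman r / t / df / p per group, in a fixed presentation order.

    Flagged (excluded) records are dropped first; groups below ``min_n``
    usable records produce an undefined (NaN) row rather than a fragile
    estimate. Exclusion counts are reported per group.
    """
    usable = dyads[~dyads["excluded"]]
    rows = []
    for name, mask in _group_masks(dyads, grouping).items():
        sub = usable[mask.reindex(usable.index, fill_value=False)]
        n_excl = int((dyads["excluded"] & mask).sum())
        if len(sub) < max(min_n, 3):
            rows.append(
                {"group": name, "r": np.nan, "t": np.nan, "df": len(sub) - 2,
                 "p": np.nan, "n": len(sub), "n_excluded": n_excl}
            )
            continue
        res = correlate(sub[covariate], sub[response], group=name)
        rows.append(
            {"group": name, "r": res.r, "t": res.t, "df": res.df, "p": res.p,
             "n": res.n, "n_excluded": n_excl}
        )
    order = {g: i for i, g in enumerate(GROUP_ORDER[grouping])}
    out = pd.DataFrame(rows)
    return out.sort_values("group", key=lambda s: s.map(order)).reset_index(drop=True)
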