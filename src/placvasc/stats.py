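"""Rank-based statistics for the density tables.

Spearman rank correlation (density vs normalised location), Kruskal-Wallis
across placentas with Dunn's pairwise post-hoc under a Bonferroni
correction, and mean/SD/median/IQR descriptives.  Significance is assessed
at alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    r_s: float
    p: float
    n: int


@dataclass
class GroupTestResult:
    """Kruskal-Wallis H (chi-squared approximation) with Dunn's post-hoc."""

    H: float
    df: int
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj


def spearman(x, y) -> CorrelationResult:
    """Two-sided Spearman rank correlation with midrank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must be paired")
    if len(x) < 3:
        raise DataError("need at least 3 paired observations")
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def kruskal_wallis_dunn(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's z per pair, Bonferroni-
    adjusted over all unordered pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 2:
        raise DataError("need at least two groups")
    samples = [values[groups == g] for g in names]
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    H, p = sps.kruskal(*samples)
    df = len(names) - 1

    # Dunn's procedure on the pooled midranks with tie correction
    ranks = sps.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: int((groups == g).sum()) for g in names}
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_raw * len(pairs)),
            }
        )
    return GroupTestResult(float(H), df, float(p), pd.DataFrame(rows))


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float  # sample (n-1) estimator; NaN (flagged) for n < 2
    min: float
    max: float
    median: float
    iqr: float

    @property
    def sd_defined(self) -> bool:
        return np.isfinite(self.sd)


def summarise(values) -> SummaryStats:
    """Mean +/- SD, range, median and IQR (linear-interpolation quantiles)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise DataError("cannot summarise an empty sample")
    q25, q75 = np.percentile(values, [25, 75])
    return SummaryStats(
        n=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
        min=float(values.min()),
        max=float(values.max()),
        median=float(np.median(values)),
        iqr=float(q75 - q25),
    )


def density_location_report(blocks: pd.DataFrame) -> dict:
    """The standard statistical report for a per-block density table
    (columns placenta_id, normalised_location, density_pct)."""
    corr = spearman(blocks["normalised_location"], blocks["density_pct"])
    out = {
        "n_blocks": int(len(blocks)),
        "spearman_r_s": corr.r_s,
        "spearman_p": corr.p,
        "density_summary": summarise(blocks["density_pct"]).__dict__,
    }
    counts = blocks.groupby("placenta_id").size()
    if (counts >= 2).sum() >= 2:
        usable = blocks[blocks["placenta_id"].isin(counts[counts >= 2].index)]
        kw = kruskal_wallis_dunn(usable["density_pct"], usable["placenta_id"])
        out["kruskal_wallis"] = {
            "H": kw.H,
            "df": kw.df,
            "p": kw.p,
            "significant_pairs": kw.pairwise[kw.pairwise["p_adj"] < ALPHA][
                ["group_a", "group_b", "p_adj"]
            ].to_dict("records"),
        }
    return out
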