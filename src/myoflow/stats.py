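"""Group-level nonparametric comparison of contraction metrics.

Observations are per-ROI metric values (count, duration, strength,
maximum velocity) under different treatment conditions.  The omnibus
test is Kruskal-Wallis (rank-based, tie-corrected, chi-square p-value);
pairwise follow-up is Dunn's z-test on the pooled ranks with Holm
family-wise adjustment by default, or a Tukey HSD run on the rank
transform ("rank-tukey") for users who want a Tukey-style procedure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KruskalResult",
    "compare_groups",
    "posthoc_pairwise",
    "paired_t",
    "unpaired_t",
]

logger = logging.getLogger(__name__)


@dataclass
class KruskalResult:
    statistic: float
    p_value: float
    n_groups: int
    all_identical: bool = False


def _as_groups(table) -> Dict[str, np.ndarray]:
    """Accept a mapping label -> values or a (condition, value) DataFrame."""
    if isinstance(table, pd.DataFrame):
        if not {"condition", "value"} <= set(table.columns):
            raise ValueError("table needs 'condition' and 'value' columns")
        return {str(k): g["value"].to_numpy(dtype=float)
                for k, g in table.groupby("condition", sort=True)}
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(table).items()}


def compare_groups(table) -> KruskalResult:
    """Kruskal-Wallis omnibus test across >= 2 groups (each n >= 2)."""
    groups = _as_groups(table)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = list(groups.values())
    for a in arrays:
        if len(a) < 2:
            raise ValueError("every group needs at least two observations")
        if not np.isfinite(a).all():
            raise ValueError("group values must be finite")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        logger.warning("all observations identical; H = 0, p = 1")
        return KruskalResult(statistic=0.0, p_value=1.0,
                             n_groups=len(groups), all_identical=True)
    h, p = sps.kruskal(*arrays)
    return KruskalResult(statistic=float(h), p_value=float(p),
                         n_groups=len(groups))


def _dunn(groups: Dict[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    sizes = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([groups[k] for k in labels])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    mean_rank = {}
    start = 0
    for k in labels:
        mean_rank[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n - 1)))
    var_unit = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_value": p})
    return pd.DataFrame(rows)


def _rank_tukey(groups: Dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    res = pairwise_tukeyhsd(ranks, labels)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = pd.DataFrame({
        "group_a": frame["group1"].astype(str),
        "group_b": frame["group2"].astype(str),
        "statistic": frame["meandiff"].astype(float),
        "p_value": frame["p-adj"].astype(float),
    })
    out["p_adjusted"] = out["p_value"]  # Tukey is already family-wise
    return out


def posthoc_pairwise(table, method: str = "dunn-holm",
                     omnibus: KruskalResult = None,
                     require_omnibus: bool = False) -> pd.DataFrame:
    """All-pairs rank-based comparisons with family-wise adjustment.

    method "dunn-holm" (default): Dunn z-tests with Holm correction;
    method "rank-tukey": Tukey HSD on the rank-transformed data.
    ``require_omnibus`` enforces that an omnibus result is supplied first
    (the usual protected workflow); pass the KruskalResult to satisfy it.
    """
    groups = _as_groups(table)
    if len(groups) < 2:
        raise ValueError("post hoc comparison needs at least two groups")
    if require_omnibus and omnibus is None:
        raise ValueError("run compare_groups first (or pass require_omnibus=False)")
    if method == "dunn-holm":
        out = _dunn(groups)
        out["p_adjusted"] = multipletests(out["p_value"], method="holm")[1]
        return out
    if method == "rank-tukey":
        return _rank_tukey(groups)
    raise ValueError("method must be 'dunn-holm' or 'rank-tukey'")


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Two-sample Welch t-test (thin utility for ramp-panel comparisons)."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=False)
    return float(t), float(p)


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Paired t-test (thin utility for before/after comparisons)."""
    t, p = sps.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)
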