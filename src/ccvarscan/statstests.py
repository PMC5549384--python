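"""Variant-density statistic and significance tests.

Density comparisons use the variant fraction — the number of variants in a
region divided by the region's nucleotide length — computed per cluster and
region.  Category distributions are compared with Pearson's chi-square;
per-region densities with one-way ANOVA followed by Tukey HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


def variant_fraction(variant_count: int, region_length_nt: int) -> float:
    """Variants per nucleotide of region: count / length."""
    if region_length_nt < 1:
        raise ValueError(f"region length must be >= 1, got {region_length_nt}")
    if variant_count < 0:
        raise ValueError("variant count must be non-negative")
    return variant_count / region_length_nt


def fraction_table(rows: Sequence[Tuple[str, str, int, int]]) -> pd.DataFrame:
    """Build the per-(cluster, region) variant-fraction table.

    ``rows`` are (cluster_id, region_tag, variant_count, region_length_nt).
    """
    df = pd.DataFrame(
        rows, columns=["cluster_id", "region_tag", "variant_count", "region_length_nt"]
    )
    df["fraction"] = df.apply(
        lambda r: variant_fraction(r.variant_count, r.region_length_nt), axis=1
    )
    return df


def chi_square_homogeneity(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on a contingency table.

    No continuity correction is applied.  A warning is logged when any
    expected count falls below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must have >= 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("contingency table must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero marginal row/column")
    stat, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        log.warning(
            "chi-square: %d expected counts below 5; asymptotic p unreliable",
            int((expected < 5).sum()),
        )
    return float(stat), int(df), float(p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, int, int, float]:
    """One-way ANOVA: F, df_between, df_within, p.

    Observations are cluster-level variant fractions, one group per
    context region.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        raise DegenerateInputError("zero within-group variance in every group")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values.

    Uses the Tukey–Kramer correction for unequal group sizes.  Returns a
    frame with one row per pair: group labels, mean difference and
    adjusted p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if sum(((a - a.mean()) ** 2).sum() for a in arrays) == 0.0:
        raise DegenerateInputError("zero within-group variance in every group")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_a": float(arrays[i].mean()),
                "mean_b": float(arrays[j].mean()),
                "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def density_report(fractions: pd.DataFrame) -> Dict:
    """ANOVA + Tukey across region tags of a per-cluster fraction table.

    Returns a JSON-serialisable dict with group means, the ANOVA line and
    the Tukey pairs; flags the degenerate (no-variance) case instead of
    failing.
    """
    groups: List[np.ndarray] = []
    labels: List[str] = []
    for tag, sub in fractions.groupby("region_tag", sort=False):
        labels.append(str(tag))
        groups.append(sub["fraction"].to_numpy())
    report: Dict = {
        "group_means": {
            lab: float(np.mean(g)) if len(g) else float("nan")
            for lab, g in zip(labels, groups)
        },
        "group_sizes": {lab: int(len(g)) for lab, g in zip(labels, groups)},
    }
    try:
        f, df_b, df_w, p = one_way_anova(groups)
    except (ValueError, DegenerateInputError) as exc:
        report["anova"] = {"degenerate": True, "reason": str(exc)}
        return report
    report["anova"] = {
        "F": f,
        "df_between": df_b,
        "df_within": df_w,
        "p_value": p,
        "degenerate": False,
    }
    report["tukey_hsd"] = tukey_hsd(groups, labels).to_dict(orient="records")
    return report
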