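"""Rank-test comparison of grand-average REN between seizure types.

Per patient, band and period, three comparisons are made against isolated
seizures: isolated vs cluster-first, vs cluster-non-last, and vs
cluster-last. Each cell is a two-sided Wilcoxon rank-sum (Mann-Whitney)
test; all cells across patients, bands, periods and comparisons form a
single family corrected by Benjamini-Hochberg FDR. Significant cells are
tallied by which group had the higher median (``cluster_higher`` vs
``isolated_higher``), split by period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .preprocess import PERIODS

logger = logging.getLogger(__name__)

#: The three seizure-type comparisons, each against isolated seizures.
COMPARISONS = {
    "isolated_vs_first": ("isolated", "cluster_first"),
    "isolated_vs_non_last": ("isolated", "cluster_non_last"),
    "isolated_vs_last": ("isolated", "cluster_last"),
}

#: Exact rank-sum enumeration below this per-group size (ties force asymptotic).
EXACT_N_MAX = 20


@dataclass(frozen=True)
class ComparisonCell:
    """One (patient, band, period, comparison) test result."""

    patient_id: str
    band: str
    period: str
    comparison: str
    n_a: int
    n_b: int
    p_raw: float | None  # None = untestable (a group with < 2 values)
    p_adj: float | None = None
    significant: bool = False
    direction: str | None = None  # cluster_higher | isolated_higher


def wilcoxon_cell(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, str | None]:
    """Two-sided rank-sum p-value and median direction for one cell.

    ``group_a`` is the isolated group, ``group_b`` the cluster group; the
    direction reports which group's median is higher (``None`` on exact
    median tie). Exact enumeration is used for small tie-free samples, a
    seeded permutation null for small tied samples, and the tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values to be testable")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_N_MAX:
        if has_ties:
            # exact enumeration assumes no ties; a seeded permutation null
            # handles tied data exactly (exhaustively when feasible)
            method = sstats.PermutationMethod(
                n_resamples=20000, rng=np.random.default_rng(0)
            )
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b > med_a:
        direction = "cluster_higher"
    elif med_a > med_b:
        direction = "isolated_higher"
    else:
        direction = None
    return float(res.pvalue), direction


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one pooled family.

    Returns (adjusted p-values, reject flags at level ``q``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def compare_groups(
    features: pd.DataFrame,
    bands: Sequence[str],
    q: float = 0.05,
    family: str = "pooled",
) -> list[ComparisonCell]:
    """All rank-sum cells over a feature table, FDR-adjusted.

    ``features`` must carry ``patient_id``, ``category``, ``is_cluster_first``
    and the ``ga_ren_<band>_<period>`` columns. The BH family is pooled over
    all patients x bands x periods x comparisons by default
    (``family='per_patient'`` adjusts within each patient instead).
    """
    cells: list[ComparisonCell] = []
    for pid, sub in features.groupby("patient_id", sort=True):
        groups = {
            "isolated": sub[sub.category == "isolated"],
            "cluster_first": sub[sub.is_cluster_first],
            "cluster_non_last": sub[sub.category == "cluster_non_last"],
            "cluster_last": sub[sub.category == "cluster_last"],
        }
        for band in bands:
            for period in PERIODS:
                col = f"ga_ren_{band}_{period}"
                for comp, (ga, gb) in COMPARISONS.items():
                    a = groups[ga][col].dropna().to_numpy()
                    b = groups[gb][col].dropna().to_numpy()
                    if a.size < 2 or b.size < 2:
                        logger.info(
                            "%s %s %s %s: untestable (n=%d vs %d)",
                            pid, band, period, comp, a.size, b.size,
                        )
                        cells.append(
                            ComparisonCell(str(pid), band, period, comp, a.size, b.size, None)
                        )
                        continue
                    p_raw, direction = wilcoxon_cell(a, b)
                    cells.append(
                        ComparisonCell(
                            str(pid), band, period, comp, a.size, b.size,
                            p_raw, direction=direction,
                        )
                    )
    return _adjust_cells(cells, q, family)


def _adjust_cells(cells: list[ComparisonCell], q: float, family: str) -> list[ComparisonCell]:
    if family not in ("pooled", "per_patient"):
        raise ValueError(f"unknown family {family!r}")
    out = list(cells)
    if family == "pooled":
        groups = {"all": [i for i, c in enumerate(cells) if c.p_raw is not None]}
    else:
        groups = {}
        for i, c in enumerate(cells):
            if c.p_raw is not None:
                groups.setdefault(c.patient_id, []).append(i)
    for idx in groups.values():
        p_adj, reject = fdr_adjust([cells[i].p_raw for i in idx], q=q)
        for j, i in enumerate(idx):
            c = cells[i]
            # a cell's direction is only meaningful once it is significant
            out[i] = replace(
                c,
                p_adj=float(p_adj[j]),
                significant=bool(reject[j]),
                direction=c.direction if reject[j] else None,
            )
    return out


def direction_tally(cells: Sequence[ComparisonCell]) -> pd.DataFrame:
    """Counts of significant cells by period and median direction."""
    rows = []
    for period in PERIODS:
        sig = [c for c in cells if c.period == period and c.significant]
        rows.append(
            {
                "period": period,
                "cluster_higher": sum(c.direction == "cluster_higher" for c in sig),
                "isolated_higher": sum(c.direction == "isolated_higher" for c in sig),
            }
        )
    return pd.DataFrame(rows)


def cells_to_frame(cells: Sequence[ComparisonCell]) -> pd.DataFrame:
    """Tidy CSV-ready table of all comparison cells."""
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cells],
            "band": [c.band for c in cells],
            "period": [c.period for c in cells],
            "comparison": [c.comparison for c in cells],
            "n_isolated": [c.n_a for c in cells],
            "n_cluster": [c.n_b for c in cells],
            "p_raw": [c.p_raw for c in cells],
            "p_adj": [c.p_adj for c in cells],
            "significant": [c.significant for c in cells],
            "direction": [c.direction for c in cells],
        }
    )
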