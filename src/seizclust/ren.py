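"""Relative entropy (REN) between channel pairs, and the per-seizure features.

REN quantifies how dissimilar the amplitude distributions of two channels
are within a short segment. For channels x and y, amplitude histograms p and
q are estimated on shared equal-width bins spanning the pooled range of both
series, and

    REN(x, y) = max( KL(p || q), KL(q || p) )        [nats]

where KL is the Kullback-Leibler divergence. Taking the maximum symmetrizes
the nonsymmetric divergence. Because every series was normalized to zero
mean and unit variance beforehand, REN responds to differences in
distribution *shape* (tail weight, skew, multimodality), not to amplitude
scale.

Per seizure, REN values over all channel pairs and all segments of a band
and period are averaged into the *grand average REN*; the 5 bands x 2
periods grand averages form the 10-dimensional feature vector used for
statistics and prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import PERIODS, SegmentTensor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RENConfig:
    """Histogram estimator settings for REN.

    ``n_bins`` equal-width bins over the pooled min-max of the two series
    (10 bins for 1000-sample segments gives ~100 expected counts per bin);
    ``smoothing_eps`` pseudo-probability is added to every bin before
    renormalization so that empty bins never produce infinite divergences.
    Logs are natural: REN is reported in nats.
    """

    n_bins: int = 10
    smoothing_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.smoothing_eps > 0:
            raise ValueError("smoothing_eps must be positive")


class DegenerateSeriesError(ValueError):
    """Raised when an amplitude distribution cannot be estimated."""


def shared_edges(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin edges spanning the pooled range of two series."""
    lo = min(float(x.min()), float(y.min()))
    hi = max(float(x.max()), float(y.max()))
    if not hi > lo:
        raise DegenerateSeriesError("pooled range is a single point (constant series)")
    return np.linspace(lo, hi, n_bins + 1)


def amplitude_distribution(
    x: np.ndarray, cfg: RENConfig, edges: np.ndarray
) -> np.ndarray:
    """Smoothed amplitude histogram of one series on the given edges.

    Returns a probability vector: counts normalized, plus ``smoothing_eps``
    per bin, renormalized.
    """
    x = np.asarray(x)
    if x.size < cfg.n_bins:
        raise DegenerateSeriesError(
            f"cannot estimate a {cfg.n_bins}-bin distribution from {x.size} samples"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    counts, _ = np.histogram(x, bins=edges)
    p = counts / counts.sum() + cfg.smoothing_eps
    return p / p.sum()


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * (np.log(p) - np.log(q))))


def relative_entropy(x: np.ndarray, y: np.ndarray, cfg: RENConfig | None = None) -> float:
    """REN of two normalized series: max of the two directed KL divergences."""
    cfg = cfg or RENConfig()
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    edges = shared_edges(x, y, cfg.n_bins)
    p = amplitude_distribution(x, cfg, edges)
    q = amplitude_distribution(y, cfg, edges)
    return max(_kl(p, q), _kl(q, p))


@dataclass
class RENResult:
    """REN values of one seizure period: [segment, channel pair, band].

    Invalid (degenerate) segments carry NaN rows and are excluded from
    averages. ``pairs`` lists the unordered channel-index pairs (66 for 12
    bipolar channels).
    """

    seizure_index: int
    period: str
    values: np.ndarray
    pairs: list[tuple[int, int]]
    band_names: tuple[str, ...]


def ren_all_pairs(seg: SegmentTensor, cfg: RENConfig | None = None) -> RENResult:
    """REN for every unordered channel pair, per segment and band.

    Each channel's segment series is sorted once; per pair, the shared-edge
    histograms are then order-statistics lookups, which makes the all-pairs
    sweep cheap without changing the estimate.
    """
    cfg = cfg or RENConfig()
    n_seg, n_ch, n_band, n_samp = seg.data.shape
    pairs = list(combinations(range(n_ch), 2))
    n_pairs = len(pairs)
    n_bins = cfg.n_bins
    values = np.full((n_seg, n_pairs, n_band), np.nan)
    eps = cfg.smoothing_eps

    ia = np.array([a for a, _ in pairs])
    ib = np.array([b for _, b in pairs])
    rows_a = [np.flatnonzero(ia == c) for c in range(n_ch)]
    rows_b = [np.flatnonzero(ib == c) for c in range(n_ch)]
    inner = np.arange(1, n_bins, dtype=float)  # internal edge indices

    n_skipped = 0
    for si in range(n_seg):
        if not seg.valid[si]:
            n_skipped += 1
            continue
        for bi in range(n_band):
            sorted_ch = np.sort(seg.data[si, :, bi, :], axis=1)
            mins = sorted_ch[:, 0]
            maxs = sorted_ch[:, -1]
            lo = np.minimum(mins[ia], mins[ib])
            hi = np.maximum(maxs[ia], maxs[ib])
            ok = hi > lo  # constant pooled range: REN undefined, leave NaN
            # internal bin edges, bit-identical to np.linspace(lo, hi, n+1)[1:-1]
            step = (hi - lo) / n_bins
            edges = lo[:, None] + step[:, None] * inner
            counts_a = np.empty((n_pairs, n_bins))
            counts_b = np.empty((n_pairs, n_bins))
            for c in range(n_ch):
                ra, rb = rows_a[c], rows_b[c]
                queries = np.concatenate([edges[ra], edges[rb]]).ravel()
                cut = np.searchsorted(sorted_ch[c], queries, side="left").reshape(
                    -1, n_bins - 1
                )
                bounds = np.concatenate(
                    [
                        np.zeros((cut.shape[0], 1), dtype=int),
                        cut,
                        np.full((cut.shape[0], 1), n_samp),
                    ],
                    axis=1,
                )
                counts = np.diff(bounds, axis=1)
                counts_a[ra] = counts[: len(ra)]
                counts_b[rb] = counts[len(ra):]
            p = counts_a / n_samp + eps
            p /= p.sum(axis=1, keepdims=True)
            q = counts_b / n_samp + eps
            q /= q.sum(axis=1, keepdims=True)
            lp = np.log(p)
            lq = np.log(q)
            kl_pq = np.sum(p * (lp - lq), axis=1)
            kl_qp = np.sum(q * (lq - lp), axis=1)
            ren = np.maximum(kl_pq, kl_qp)
            values[si, ok, bi] = ren[ok]
    if n_skipped:
        logger.info(
            "seizure %d %s: skipped %d invalid segment(s) in REN",
            seg.seizure_index, seg.period, n_skipped,
        )
    return RENResult(seg.seizure_index, seg.period, values, pairs, seg.band_names)


def grand_average(ren: RENResult) -> dict[str, float]:
    """Mean REN over all pairs and segments, per band; NaN-aware.

    Returns ``{band_name: mean}``; a band with no contributing entries is
    omitted (period had zero usable segments).
    """
    out: dict[str, float] = {}
    for bi, band in enumerate(ren.band_names):
        vals = ren.values[:, :, bi]
        finite = np.isfinite(vals)
        if finite.any():
            out[band] = float(vals[finite].mean())
    return out


def feature_columns(band_names: Sequence[str], periods: Sequence[str] = PERIODS) -> list[str]:
    """Names of the grand-average REN feature columns, period-major."""
    return [f"ga_ren_{band}_{period}" for period in periods for band in band_names]


def assemble_features(
    per_seizure: Mapping[int, Mapping[str, Mapping[str, float]]],
    annotations: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Build the per-seizure feature table (one 10-feature row per seizure).

    Parameters
    ----------
    per_seizure : mapping seizure_index -> period -> band -> grand average.
    annotations : the patient's annotation rows (onset order).
    labels : taxonomy label frame (from ``taxonomy.labels_to_frame``).

    Rows missing any of the band x period features (e.g. a sub-segment-length
    ictal window) are dropped with a log message; a seizure with both periods
    empty never appears. Row order follows onset time.
    """
    ann = annotations.reset_index(drop=True)
    lab = labels.set_index("seizure_index")
    band_names = None
    rows = []
    dropped = []
    for idx in range(len(ann)):
        ga = per_seizure.get(idx, {})
        if not ga:
            dropped.append(idx)
            continue
        if band_names is None:
            for period in PERIODS:
                if period in ga:
                    band_names = tuple(ga[period].keys())
                    break
        row: dict[str, object] = {
            "patient_id": ann.loc[idx, "patient_id"],
            "seizure_index": idx,
            "onset_s": ann.loc[idx, "onset_s"],
            "category": lab.loc[idx, "category"],
            "is_cluster_first": bool(lab.loc[idx, "is_cluster_first"]),
        }
        complete = True
        for period in PERIODS:
            for band in band_names or ():
                val = ga.get(period, {}).get(band)
                if val is None:
                    complete = False
                row[f"ga_ren_{band}_{period}"] = np.nan if val is None else val
        if not complete:
            dropped.append(idx)
            continue
        rows.append(row)
    if dropped:
        logger.info(
            "dropped %d seizure(s) with incomplete features: %s", len(dropped), dropped
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return df
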