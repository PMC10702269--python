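"""From raw contact signals to normalized band-filtered 2.5 s segments.

The stages mirror a standard clinical iEEG feature pipeline:

1. **Bipolar montage** — each derived channel is the difference of two
   consecutive contacts within an electrode array, suppressing artifacts
   common to neighbouring contacts. The default layout (2 lead assemblies ×
   2 arrays × 4 contacts) yields 12 bipolar channels.
2. **Period windows** — per seizure, an *ictal* window [onset, offset] and a
   *near-seizure* window covering up to 10 minutes before onset, truncated
   at the previous seizure's termination.
3. **Segmentation and filtering** — each window is filtered into the five
   physiologic bands (delta through gamma) with zero-phase order-2
   Butterworth band-passes, cut into non-overlapping 2.5 s segments aligned
   to seizure onset, and every (segment, channel, band) series is independently
   normalized to zero mean and unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .events import SeizureEvent, check_ordered

logger = logging.getLogger(__name__)

Period = Literal["near_seizure", "ictal"]
PERIODS = ("near_seizure", "ictal")

#: Length of an analysis segment in seconds.
SEGMENT_LEN_S = 2.5
#: Maximum pre-ictal window length in seconds (10 minutes).
NEAR_WINDOW_S = 600.0
#: Variance below which a filtered series is considered degenerate.
_DEGENERATE_VAR = 1e-24


@dataclass(frozen=True)
class MontageLayout:
    """Contact geometry and the bipolar pairs it induces.

    Contacts are numbered assembly-major, then array, then contact along the
    array; bipolar pairs are consecutive contacts within each array.
    """

    assemblies: int = 2
    arrays_per_assembly: int = 2
    contacts_per_array: int = 4

    def __post_init__(self) -> None:
        for name in ("assemblies", "arrays_per_assembly", "contacts_per_array"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_contacts(self) -> int:
        return self.assemblies * self.arrays_per_assembly * self.contacts_per_array

    @property
    def bipolar_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        n_arrays = self.assemblies * self.arrays_per_assembly
        for a in range(n_arrays):
            base = a * self.contacts_per_array
            for k in range(self.contacts_per_array - 1):
                pairs.append((base + k, base + k + 1))
        return pairs

    @property
    def n_bipolar(self) -> int:
        return len(self.bipolar_pairs)


@dataclass(frozen=True)
class BandSpec:
    """One physiologic frequency band (edges in Hz)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 < lo < hi, got {self.lo}, {self.hi}")


#: The five standard physiologic bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 25.0),
    BandSpec("gamma", 25.0, 45.0),
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


@dataclass(frozen=True)
class PeriodWindow:
    """Absolute-time window of one seizure's ictal or near-seizure period."""

    seizure_index: int
    period: Period
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("window end precedes start")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SegmentTensor:
    """Normalized band-filtered segments of one seizure period.

    ``data`` is indexed [segment, bipolar channel, band, sample]; ``valid``
    flags segments in which every (channel, band) series was non-degenerate.
    Segment 0 is the one nearest the seizure onset for both periods.
    """

    seizure_index: int
    period: Period
    data: np.ndarray
    fs: float
    band_names: tuple[str, ...]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    segment_len_s: float = SEGMENT_LEN_S

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be [segment, channel, band, sample]")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def make_bipolar(raw: np.ndarray, layout: MontageLayout | None = None) -> np.ndarray:
    """Re-reference contacts to the consecutive-pair bipolar montage.

    Parameters
    ----------
    raw : array, shape (n_contacts, n_samples)
    layout : MontageLayout, optional

    Returns
    -------
    array, shape (n_bipolar, n_samples)
        Row ``k`` is ``contact[i] - contact[j]`` for the k-th pair.
    """
    layout = layout or MontageLayout()
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[0] != layout.n_contacts:
        raise ValueError(
            f"expected {layout.n_contacts} contacts, got array of shape {raw.shape}"
        )
    pairs = layout.bipolar_pairs
    idx_i = [i for i, _ in pairs]
    idx_j = [j for _, j in pairs]
    return raw[idx_i] - raw[idx_j]


def extract_windows(
    events: Sequence[SeizureEvent],
    near_window_s: float = NEAR_WINDOW_S,
    recording_start_s: float = 0.0,
) -> list[PeriodWindow]:
    """Ictal and near-seizure windows for every seizure of one patient.

    The near-seizure window ends at onset and extends back by at most
    ``near_window_s`` (10 min default), truncated at the previous seizure's
    offset (and at the recording start). A zero-length near-seizure window is
    allowed and simply yields no segments.
    """
    events = list(events)
    check_ordered(events)
    windows: list[PeriodWindow] = []
    prev_offset = recording_start_s
    for i, ev in enumerate(events):
        near_start = max(ev.onset_s - near_window_s, prev_offset)
        windows.append(PeriodWindow(i, "near_seizure", near_start, ev.onset_s))
        windows.append(PeriodWindow(i, "ictal", ev.onset_s, ev.offset_s))
        prev_offset = ev.offset_s
    return windows


def band_sos(band: BandSpec, fs: float, order: int = 2) -> np.ndarray:
    """Second-order-sections of the order-2 Butterworth band-pass."""
    nyq = fs / 2.0
    if not band.hi < nyq:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def segment_and_filter(
    window_signal: np.ndarray,
    window: PeriodWindow,
    fs: float,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    segment_len_s: float = SEGMENT_LEN_S,
) -> SegmentTensor:
    """Filter one period window into bands and cut normalized segments.

    ``window_signal`` holds the bipolar channels over exactly the window
    [start_s, end_s). Filtering is zero-phase (forward-backward) over the
    whole window, then segments tile from the onset boundary: backward from
    the window end for the near-seizure period, forward from the window
    start for the ictal period, so the segment boundary nearest the onset
    coincides with the onset sample; the partial remainder at the far end is
    dropped. Each retained (segment, channel, band) series is normalized to
    zero mean, unit variance; segments containing a constant series are
    flagged invalid and excluded downstream.
    """
    sig = np.asarray(window_signal, dtype=np.float64)
    if sig.ndim != 2:
        raise ValueError("window_signal must be (channels, samples)")
    n_ch, n_samp = sig.shape
    seg_len = int(round(segment_len_s * fs))
    n_seg = n_samp // seg_len
    band_names = tuple(b.name for b in bands)

    if n_seg == 0:
        if window.period == "ictal" and window.length_s > 0:
            logger.info(
                "seizure %d: ictal window of %.1f s shorter than one segment; "
                "excluded from ictal averages",
                window.seizure_index,
                window.length_s,
            )
        data = np.empty((0, n_ch, len(bands), seg_len))
        return SegmentTensor(
            window.seizure_index, window.period, data, fs, band_names,
            valid=np.empty(0, dtype=bool), segment_len_s=segment_len_s,
        )

    used = n_seg * seg_len
    if window.period == "near_seizure":
        sig = sig[:, n_samp - used:]  # tile backward from onset
    else:
        sig = sig[:, :used]  # tile forward from onset

    # filter whole window per band (all channels at once), then segment
    data = np.empty((n_seg, n_ch, len(bands), seg_len))
    for bi, band in enumerate(bands):
        sos = band_sos(band, fs)
        filt = sps.sosfiltfilt(sos, sig, axis=1)
        segs = filt.reshape(n_ch, n_seg, seg_len).transpose(1, 0, 2)
        data[:, :, bi, :] = segs

    # order segments nearest-onset-first for both periods
    if window.period == "near_seizure":
        data = data[::-1].copy()

    mean = data.mean(axis=3, keepdims=True)
    var = data.var(axis=3, keepdims=True)
    degenerate = (var < _DEGENERATE_VAR).any(axis=(1, 2, 3))
    safe_var = np.where(var < _DEGENERATE_VAR, 1.0, var)
    data = (data - mean) / np.sqrt(safe_var)
    valid = ~degenerate
    if degenerate.any():
        logger.info(
            "seizure %d %s: excluded %d degenerate segment(s)",
            window.seizure_index, window.period, int(degenerate.sum()),
        )
    return SegmentTensor(
        window.seizure_index, window.period, data, fs, band_names,
        valid=valid, segment_len_s=segment_len_s,
    )
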