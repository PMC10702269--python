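"""Synthetic multi-patient iEEG with known seizure-cluster structure.

The generator stands in for a chronic ambulatory recording: per patient it
produces (a) a seizure *schedule* with ground-truth taxonomy — isolated
events and cluster blocks laid out by an alternating-renewal process whose
gaps straddle the ISI cutoff by construction, so threshold labelling must
recover the truth exactly — and (b) multichannel *signals* around each
seizure with a controllable between-type difference in cross-channel
amplitude-distribution divergence.

Background model
    Each contact is a sum of independent band-limited Gaussian noise
    components, one per physiologic band, with a 1/f-like amplitude profile.

Effect mechanism
    Within each short gain block (0.25 s), every contact's band component is
    multiplied by an independent log-normal gain. The log-spread of these
    gains makes the segment amplitude distribution a Gaussian scale mixture:
    larger spread means heavier tails and larger channel-to-channel shape
    differences, hence larger REN. Seizure type modulates the spread in the
    chosen bands: cluster seizures get an inflated spread near seizure
    (higher REN) and cluster-non-last seizures a deflated spread ictally
    (lower REN). With both effects at zero the two types are statistically
    identical. Because the downstream pipeline normalizes every segment,
    only this distribution-shape channel — not mean or total power — carries
    the effect.

Ictal periods additionally get an amplitude envelope ramp (2-5x background)
so that seizure segments are visibly distinct; no spike morphology is
modelled because REN does not require it.

Signals are held sparsely: only the near-seizure + ictal windows are
materialized as chunks on the absolute timeline; unvisited background can be
regenerated deterministically on demand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .events import SeizureEvent, events_to_frame
from .preprocess import DEFAULT_BANDS, BandSpec, MontageLayout

logger = logging.getLogger(__name__)

#: 1/f-like relative amplitudes of the background band components.
DEFAULT_BAND_AMPLITUDES: Mapping[str, float] = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 0.6,
    "beta": 0.5,
    "gamma": 0.4,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Rates and sizes default to the regime of a long ambulatory monitoring
    study: ~0.075 isolated events and ~0.085 clusters per patient-day,
    cluster sizes of a truncated geometric with mean ~8, seizure durations
    log-normal with mean 39 s and SD 63.6 s, 16 contacts at 400 Hz in a
    2-assembly x 2-array x 4-contact layout. ``effect_near`` and
    ``effect_ictal`` are the dimensionless type effects: the near-seizure
    gain spread of cluster seizures is ``base_spread * (1 + effect_near)``
    and the ictal spread of cluster-non-last seizures is
    ``base_spread / (1 + effect_ictal)``, in ``effect_bands`` only.
    """

    n_patients: int = 1
    recording_days: float = 250.0
    fs: float = 400.0
    layout: MontageLayout = field(default_factory=MontageLayout)
    isolated_rate: float = 0.075  # isolated events / day
    cluster_rate: float = 0.085  # cluster blocks / day
    cluster_size_p: float = 0.15  # size = 1 + Geometric(p), i.e. >= 2
    max_cluster_size: int = 30
    intra_cluster_isi_mean_h: float = 2.0
    inter_event_gap_extra_mean_h: float = 126.0  # gap = threshold + Exp(mean)
    isi_threshold_h: float = 24.0
    seizure_duration_mean_s: float = 39.0
    seizure_duration_sd_s: float = 63.6
    duration_range_s: tuple[float, float] = (1.0, 300.0)
    effect_near: float = 0.0
    effect_ictal: float = 0.0
    effect_bands: tuple[str, ...] = ("beta", "gamma")
    base_spread: float = 0.3
    gain_block_s: float = 0.25
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    ictal_gain: tuple[float, float] = (2.0, 5.0)
    active_window_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "recording_days": self.recording_days,
            "fs": self.fs,
            "isolated_rate": self.isolated_rate + self.cluster_rate,
            "intra_cluster_isi_mean_h": self.intra_cluster_isi_mean_h,
            "inter_event_gap_extra_mean_h": self.inter_event_gap_extra_mean_h,
            "isi_threshold_h": self.isi_threshold_h,
            "seizure_duration_mean_s": self.seizure_duration_mean_s,
            "base_spread": self.base_spread,
            "gain_block_s": self.gain_block_s,
            "active_window_s": self.active_window_s,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.effect_near < 0 or self.effect_ictal < 0:
            raise ValueError("effects must be >= 0")
        if not 0 < self.cluster_size_p <= 1:
            raise ValueError("cluster_size_p must be in (0, 1]")
        unknown = set(self.effect_bands) - {b.name for b in self.bands}
        if unknown:
            raise ValueError(f"effect_bands not in bands: {sorted(unknown)}")

    @property
    def horizon_h(self) -> float:
        return self.recording_days * 24.0

    def _lognorm_params(self) -> tuple[float, float]:
        m, s = self.seizure_duration_mean_s, self.seizure_duration_sd_s
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class SeizureTruth:
    """Generator-side ground truth for one seizure."""

    category: str  # isolated | cluster_non_last | cluster_last
    is_cluster_first: bool
    cluster_id: int | None
    #: spread multiplier actually applied, per (period, band)
    effects: Mapping[str, Mapping[str, float]]


class Recording:
    """Sparse multichannel recording: materialized chunks on a timeline.

    ``chunks`` is an ordered list of ``(start_sample, array)`` with
    non-overlapping float32 arrays of shape (n_contacts, n). ``slice``
    assembles any requested span; spans outside every chunk are filled with
    deterministic white background noise matched to the total background
    power (seeded by position, so reads are reproducible).
    """

    def __init__(
        self,
        fs: float,
        n_contacts: int,
        duration_s: float,
        chunks: list[tuple[int, np.ndarray]],
        fill_scale: float = 1.0,
        fill_seed: int = 0,
    ) -> None:
        self.fs = fs
        self.n_contacts = n_contacts
        self.duration_s = duration_s
        self.chunks = sorted(chunks, key=lambda c: c[0])
        self.fill_scale = fill_scale
        self.fill_seed = fill_seed
        for (s0, a0), (s1, _) in zip(self.chunks, self.chunks[1:]):
            if s0 + a0.shape[1] > s1:
                raise ValueError("recording chunks overlap")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def sample_index(self, t_s: float) -> int:
        return int(round(t_s * self.fs))

    def _fill(self, start: int, n: int) -> np.ndarray:
        rng = np.random.default_rng((self.fill_seed, start))
        return (self.fill_scale * rng.standard_normal((self.n_contacts, n))).astype(
            np.float32
        )

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Signals over [start_s, end_s) as float64 (contacts x samples)."""
        i0 = self.sample_index(start_s)
        i1 = self.sample_index(end_s)
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"requested span [{start_s}, {end_s}) s outside the recording"
            )
        out = np.empty((self.n_contacts, i1 - i0), dtype=np.float64)
        cursor = i0
        for cstart, arr in self.chunks:
            cend = cstart + arr.shape[1]
            if cend <= cursor or cstart >= i1:
                continue
            if cstart > cursor:
                out[:, cursor - i0 : cstart - i0] = self._fill(cursor, cstart - cursor)
                cursor = cstart
            take0 = cursor - cstart
            take1 = min(cend, i1) - cstart
            out[:, cursor - i0 : cursor - i0 + (take1 - take0)] = arr[:, take0:take1]
            cursor = cstart + take1
            if cursor >= i1:
                break
        if cursor < i1:
            out[:, cursor - i0 :] = self._fill(cursor, i1 - cursor)
        return out


@dataclass
class SyntheticDataset:
    """One simulated cohort: recordings, annotations and ground truth."""

    config: SimConfig
    recordings: dict[str, Recording]
    annotations: pd.DataFrame
    truth: dict[str, list[SeizureTruth]]

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.recordings)

    def patient_events(self, patient_id: str) -> list[SeizureEvent]:
        sub = self.annotations[self.annotations.patient_id == patient_id]
        return [
            SeizureEvent(patient_id, float(r.onset_s), float(r.offset_s))
            for r in sub.itertuples(index=False)
        ]


def patient_id(index: int) -> str:
    return f"p{index:02d}"


def simulate_schedule(
    cfg: SimConfig, patient: int = 0
) -> tuple[list[SeizureEvent], list[SeizureTruth]]:
    """Draw one patient's seizure schedule with ground-truth taxonomy.

    Alternating renewal: blocks (a single isolated seizure, or a cluster of
    >= 2 seizures) separated by gaps strictly above the ISI cutoff; within a
    cluster, offset-to-onset intervals strictly below the cutoff. Applying
    threshold labelling at ``cfg.isi_threshold_h`` therefore reproduces the
    generated categories exactly (under either ISI reference, since
    durations are far smaller than the cutoff).
    """
    rng = np.random.default_rng((cfg.seed, patient, 1))
    pid = patient_id(patient)
    p_cluster = cfg.cluster_rate / (cfg.cluster_rate + cfg.isolated_rate)
    mu, sigma = cfg._lognorm_params()
    lo_d, hi_d = cfg.duration_range_s

    def duration_h() -> float:
        return float(np.clip(rng.lognormal(mu, sigma), lo_d, hi_d)) / 3600.0

    def intra_isi_h() -> float:
        raw = rng.exponential(cfg.intra_cluster_isi_mean_h)
        return float(np.clip(raw, 0.02, 0.95 * cfg.isi_threshold_h))

    events: list[SeizureEvent] = []
    truth: list[SeizureTruth] = []
    t = 0.0  # hours; last offset (or recording start)
    cluster_counter = -1
    while True:
        gap = cfg.isi_threshold_h + rng.exponential(cfg.inter_event_gap_extra_mean_h)
        onset = t + gap
        if rng.random() < p_cluster:
            size = min(1 + int(rng.geometric(cfg.cluster_size_p)), cfg.max_cluster_size)
        else:
            size = 1
        block: list[tuple[float, float]] = []
        cur = onset
        for k in range(size):
            d = duration_h()
            block.append((cur, cur + d))
            if k < size - 1:
                cur = cur + d + intra_isi_h()
        if block[-1][1] > cfg.horizon_h:
            break
        if size == 1:
            truth.append(SeizureTruth("isolated", False, None, {}))
        else:
            cluster_counter += 1
            for k in range(size):
                cat = "cluster_last" if k == size - 1 else "cluster_non_last"
                truth.append(SeizureTruth(cat, k == 0, cluster_counter, {}))
        events.extend(
            SeizureEvent(pid, on * 3600.0, off * 3600.0) for on, off in block
        )
        t = block[-1][1]
    if not events:
        raise ValueError(
            f"recording of {cfg.recording_days} days too short to place any seizure"
        )
    return events, truth


def _band_noise(
    rng: np.random.Generator, sos: np.ndarray, n_contacts: int, n: int
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, one row per contact."""
    white = rng.standard_normal((n_contacts, n))
    x = sps.sosfiltfilt(sos, white, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _block_gains(
    rng: np.random.Generator,
    spread: float,
    n_contacts: int,
    n: int,
    block_len: int,
    align: str,
) -> np.ndarray:
    """Per-contact piecewise-constant log-normal gains over n samples.

    Blocks tile from the onset boundary (``align='end'`` for the pre-onset
    stretch, ``'start'`` for the ictal stretch) so that block edges coincide
    with the downstream segment grid. E[gain] = 1 for every spread.
    """
    if spread == 0.0:
        return np.ones((n_contacts, n))
    n_blocks = -(-n // block_len)
    z = rng.standard_normal((n_contacts, n_blocks))
    g = np.exp(spread * z - spread**2 / 2.0)
    full = np.repeat(g, block_len, axis=1)
    return full[:, -n:] if align == "end" else full[:, :n]


def simulate_signals(
    cfg: SimConfig,
    events: Sequence[SeizureEvent],
    truth: Sequence[SeizureTruth],
    patient: int = 0,
) -> tuple[Recording, list[SeizureTruth]]:
    """Materialize signals around each scheduled seizure of one patient.

    Returns the recording and the truth list updated with the spread
    multipliers actually applied per (period, band).
    """
    rng = np.random.default_rng((cfg.seed, patient, 2))
    fs = cfg.fs
    n_contacts = cfg.layout.n_contacts
    block_len = max(1, int(round(cfg.gain_block_s * fs)))
    sos_by_band = {b.name: sps.butter(2, [b.lo, b.hi], "bandpass", fs=fs, output="sos") for b in cfg.bands}
    amps = {b.name: float(cfg.band_amplitudes.get(b.name, 1.0)) for b in cfg.bands}
    total_power = float(np.sqrt(sum(a**2 for a in amps.values())))

    chunks: list[tuple[int, np.ndarray]] = []
    truth_out: list[SeizureTruth] = []
    prev_offset = 0.0
    for ev, tr in zip(events, truth):
        is_cluster = tr.category != "isolated"
        near_start = max(ev.onset_s - cfg.active_window_s, prev_offset)
        i_near = int(round(near_start * fs))
        i_on = int(round(ev.onset_s * fs))
        i_off = int(round(ev.offset_s * fs))
        n_near, n_ict = i_on - i_near, i_off - i_on
        sig = np.zeros((n_contacts, n_near + n_ict))
        effects: dict[str, dict[str, float]] = {"near_seizure": {}, "ictal": {}}
        for band in cfg.bands:
            noise = _band_noise(rng, sos_by_band[band.name], n_contacts, n_near + n_ict)
            in_effect = band.name in cfg.effect_bands
            near_mult = 1.0 + cfg.effect_near if (is_cluster and in_effect) else 1.0
            ictal_mult = (
                1.0 / (1.0 + cfg.effect_ictal)
                if (tr.category == "cluster_non_last" and in_effect)
                else 1.0
            )
            effects["near_seizure"][band.name] = near_mult
            effects["ictal"][band.name] = ictal_mult
            gains = np.empty_like(sig)
            if n_near:
                gains[:, :n_near] = _block_gains(
                    rng, cfg.base_spread * near_mult, n_contacts, n_near, block_len, "end"
                )
            if n_ict:
                gains[:, n_near:] = _block_gains(
                    rng, cfg.base_spread * ictal_mult, n_contacts, n_ict, block_len, "start"
                )
            sig += amps[band.name] * gains * noise
        if n_ict:
            lo, hi = cfg.ictal_gain
            sig[:, n_near:] *= np.linspace(lo, hi, n_ict)
        chunks.append((i_near, sig.astype(np.float32)))
        truth_out.append(
            SeizureTruth(tr.category, tr.is_cluster_first, tr.cluster_id, effects)
        )
        prev_offset = ev.offset_s
    rec = Recording(
        fs,
        n_contacts,
        cfg.recording_days * 86400.0,
        chunks,
        fill_scale=total_power,
        fill_seed=int(np.random.default_rng((cfg.seed, patient, 3)).integers(2**31)),
    )
    return rec, truth_out


def simulate(cfg: SimConfig) -> SyntheticDataset:
    """Simulate the full cohort (schedules + signals for every patient)."""
    recordings: dict[str, Recording] = {}
    truth: dict[str, list[SeizureTruth]] = {}
    frames = []
    for p in range(cfg.n_patients):
        events, sched_truth = simulate_schedule(cfg, p)
        rec, full_truth = simulate_signals(cfg, events, sched_truth, p)
        pid = patient_id(p)
        recordings[pid] = rec
        truth[pid] = full_truth
        frames.append(events_to_frame(events))
        logger.info("patient %s: %d seizures simulated", pid, len(events))
    return SyntheticDataset(cfg, recordings, pd.concat(frames, ignore_index=True), truth)


# ---------------------------------------------------------------------------
# disk round trip: raw float32 binary + JSON sidecar per patient


def save_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write signals (chunked raw float32 + JSON sidecar), annotations, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.annotations.to_csv(outdir / "annotations.csv", index=False)
    truth_json = {
        pid: [
            {
                "category": t.category,
                "is_cluster_first": t.is_cluster_first,
                "cluster_id": t.cluster_id,
                "effects": t.effects,
            }
            for t in trs
        ]
        for pid, trs in ds.truth.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    for pid, rec in ds.recordings.items():
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        index = []
        with open(pdir / "signals.bin", "wb") as fh:
            offset = 0
            for start, arr in rec.chunks:
                raw = np.ascontiguousarray(arr, dtype=np.float32)
                fh.write(raw.tobytes())
                index.append(
                    {"start_sample": start, "n_samples": raw.shape[1], "byte_offset": offset}
                )
                offset += raw.nbytes
        sidecar = {
            "format": "seizclust-raw-v1",
            "dtype": "float32",
            "order": "C (contacts x samples)",
            "fs": rec.fs,
            "n_contacts": rec.n_contacts,
            "duration_s": rec.duration_s,
            "fill_scale": rec.fill_scale,
            "fill_seed": rec.fill_seed,
            "layout": asdict(ds.config.layout),
            "chunks": index,
        }
        (pdir / "signals.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(patient_dir: str | Path) -> Recording:
    """Read one patient's signals from the raw + JSON sidecar format."""
    patient_dir = Path(patient_dir)
    meta = json.loads((patient_dir / "signals.json").read_text())
    n_contacts = int(meta["n_contacts"])
    chunks = []
    with open(patient_dir / "signals.bin", "rb") as fh:
        blob = fh.read()
    for c in meta["chunks"]:
        n = int(c["n_samples"])
        off = int(c["byte_offset"])
        arr = np.frombuffer(
            blob, dtype=np.float32, count=n_contacts * n, offset=off
        ).reshape(n_contacts, n)
        chunks.append((int(c["start_sample"]), arr))
    return Recording(
        float(meta["fs"]),
        n_contacts,
        float(meta["duration_s"]),
        chunks,
        fill_scale=float(meta.get("fill_scale", 1.0)),
        fill_seed=int(meta.get("fill_seed", 0)),
    )
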