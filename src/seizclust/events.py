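"""Seizure annotations: the event container and its CSV round trip.

An annotation table is the minimal input of the whole pipeline: one row per
seizure with the patient id and the onset/offset in seconds on the absolute
recording timeline. Seizure detection itself is upstream of this package;
annotations are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ANNOTATION_COLUMNS = ["patient_id", "onset_s", "offset_s"]


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure on the absolute recording timeline."""

    patient_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"seizure offset ({self.offset_s}) must lie after onset "
                f"({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def check_ordered(events: Sequence[SeizureEvent]) -> None:
    """Raise if events are not time-ordered and non-overlapping."""
    for prev, cur in zip(events, events[1:]):
        if cur.onset_s < prev.offset_s:
            raise ValueError(
                f"events overlap or are unordered: onset {cur.onset_s} s "
                f"precedes previous offset {prev.offset_s} s"
            )


def events_to_frame(events: Iterable[SeizureEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.patient_id, e.onset_s, e.offset_s) for e in events],
        columns=ANNOTATION_COLUMNS,
    )


def frame_to_events(df: pd.DataFrame) -> list[SeizureEvent]:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    return [
        SeizureEvent(str(r.patient_id), float(r.onset_s), float(r.offset_s))
        for r in df.itertuples(index=False)
    ]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV with header ``patient_id,onset_s,offset_s``."""
    df = pd.read_csv(path)
    frame_to_events(df)  # validates schema and per-event sanity
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
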