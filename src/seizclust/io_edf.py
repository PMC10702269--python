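"""Reading real recordings from EDF.

Clinical exports commonly arrive as EDF; this thin wrapper loads one file
into the (contacts x samples) array + sampling rate the pipeline consumes.
The synthetic raw float32 + JSON sidecar format (see ``synthetic``) is the
package's native interchange format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_edf(path: str | Path) -> tuple[np.ndarray, float]:
    """Load an EDF file as (contacts x samples, sampling rate in Hz).

    Requires ``mne``; channels are returned in file order and must match
    the montage layout used downstream.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])
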