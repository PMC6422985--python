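"""Core record container for fetal heart rate (FHR) traces.

An FHR trace is a uniformly sampled beats-per-minute series (4 Hz in the
CTU-UHB database). A sample value of exactly 0 encodes signal loss
(transducer dropout), which the preprocessing stage repairs or removes.
The umbilical-artery pH measured at delivery, when available, is the
objective outcome used to label a record normal (pH >= 7.15) or
pathological.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

NORMAL = "normal"
PATHOLOGICAL = "pathological"
CLASSES = (NORMAL, PATHOLOGICAL)


@dataclass
class FHRRecord:
    """A sampled fetal heart-rate trace with outcome metadata.

    Parameters
    ----------
    record_id : str
        Unique identifier of the recording.
    samples : ndarray of float
        Heart rate in bpm at a fixed sampling rate; 0 encodes missing.
    fs : float
        Sampling frequency in Hz (CTU-UHB uses 4 Hz).
    ph : float, optional
        Umbilical-artery pH at delivery (unitless).
    label : str, optional
        ``"normal"`` or ``"pathological"``.
    """

    record_id: str
    samples: np.ndarray
    fs: float = 4.0
    ph: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.any(self.samples < 0):
            raise ValueError("samples must be >= 0 bpm (0 encodes missing)")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def with_samples(self, samples: np.ndarray) -> "FHRRecord":
        """Copy of this record carrying a new sample array."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministically derive a sub-seed from a master seed and a stage label.

    Uses SHA-256 of ``"{master_seed}:{label}"`` truncated to 31 bits so every
    pipeline stage gets an independent, reproducible stream without manual
    seed bookkeeping.
    """
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
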