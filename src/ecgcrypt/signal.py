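"""Core signal container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class ECGSignal:
    """A single-lead ECG trace.

    Parameters
    ----------
    samples : array-like of float
        Sample values in arbitrary amplitude units.
    fs : float
        Sampling rate in Hz.
    annotations : array-like of int, optional
        Ground-truth R-peak sample indices (0-based), strictly increasing.
    label : str
        Free-text label carried through I/O round trips.
    meta : dict
        Stage-specific provenance (applied filter specs, seeds, ...).
    """

    samples: np.ndarray
    fs: float
    annotations: np.ndarray | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("samples contain non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if self.annotations is not None:
            ann = np.asarray(self.annotations, dtype=int)
            if ann.size and (
                np.any(np.diff(ann) <= 0)
                or ann[0] < 0
                or ann[-1] >= self.samples.size
            ):
                raise InputError(
                    "annotations must be strictly increasing indices in [0, len)"
                )
            self.annotations = ann

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based)."""
        return np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray, **meta) -> "ECGSignal":
        """New signal with replaced samples, inheriting fs/annotations/label."""
        return ECGSignal(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            annotations=None if self.annotations is None else self.annotations.copy(),
            label=self.label,
            meta={**self.meta, **meta},
        )
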