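"""Shared containers: sensor recordings, frequency bands, ROI naming.

The analysis operates on four regions of interest — left/right subgenual
anterior cingulate cortex (sgACC) and left/right dorsolateral prefrontal
cortex (DLPFC) — and six canonical frequency bands from theta to gamma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Canonical ROI names, in the fixed (lexicographic) order used everywhere.
DEFAULT_ROI_NAMES: tuple[str, ...] = ("DLPFC_L", "DLPFC_R", "sgACC_L", "sgACC_R")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz exceeds "
                f"Nyquist for fs={fs} Hz"
            )


#: The six bands of the broadband analysis: theta, alpha, three beta
#: sub-bands and gamma.  The 13–17 Hz beta-1 band carries the group effect
#: in the planted default simulation.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta1", 13.0, 17.0),
    BandDefinition("beta2", 18.0, 24.0),
    BandDefinition("beta3", 25.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"no band named {name!r}")


def roi_pairs(roi_names=DEFAULT_ROI_NAMES) -> list[tuple[str, str]]:
    """Unordered ROI pairs in fixed lexicographic order.

    4 ROIs give 6 pairs; this ordering indexes axis 1 of every
    connectivity tensor produced by the package.
    """
    ordered = sorted(roi_names)
    return list(itertools.combinations(ordered, 2))


def pair_index(roi_a: str, roi_b: str, roi_names=DEFAULT_ROI_NAMES) -> int:
    key = tuple(sorted((roi_a, roi_b)))
    pairs = roi_pairs(roi_names)
    try:
        return pairs.index(key)
    except ValueError:
        raise KeyError(f"({roi_a}, {roi_b}) is not an ROI pair of {roi_names}") from None


@dataclass
class SensorRecording:
    """A multi-channel recording: ``data`` is channels x samples at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.ch_names:
            self.ch_names = [f"EEG{i + 1:03d}" for i in range(self.n_channels)]
        if len(self.ch_names) != self.n_channels:
            raise ValueError("channel-name count does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs
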