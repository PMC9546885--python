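"""Minimum-norm source reconstruction and ROI timeseries extraction.

The inverse is the classic Tikhonov-regularized minimum-norm estimate with a
diagonal noise model: sensor data are whitened by the per-channel noise
standard deviation, and sources are the minimum-power current distribution
explaining the whitened data,

    K = G' (G G' + lambda2 I)^-1 W,     G = W L,  W = C^{-1/2},

with identity source covariance and no depth weighting.  ``lambda2``
defaults to 1/9, the usual SNR = 3 convention for regularizing a whitened
minimum-norm operator.

Sources may carry one or three orientation components each.  Three-component
(unconstrained-orientation) sources are collapsed to a single timeseries by
the first principal component of the 3 x samples block, which preserves the
signal's phase (an amplitude-envelope analysis needs the oscillation, not
its rectified norm).  ROI timeseries are sign-aligned means of their member
source timeseries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import SensorRecording


@dataclass
class ForwardModel:
    """Lead field: ``L`` maps source components to sensors.

    ``components_per_source`` is 1 (fixed orientation) or 3 (unconstrained);
    with 3, columns of ``L`` are grouped contiguously per source.
    """

    L: np.ndarray
    components_per_source: int = 1
    sensor_labels: list[str] = field(default_factory=list)
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2 or not np.all(np.isfinite(self.L)):
            raise ValueError("lead field must be a finite 2-D matrix")
        if self.components_per_source not in (1, 3):
            raise ValueError("components_per_source must be 1 or 3")
        if self.L.shape[1] % self.components_per_source:
            raise ValueError("column count not divisible by components_per_source")
        if not self.sensor_labels:
            self.sensor_labels = [f"EEG{i + 1:03d}" for i in range(self.L.shape[0])]
        if not self.source_labels:
            self.source_labels = [f"src{i + 1:03d}" for i in range(self.n_sources)]

    @property
    def n_sensors(self) -> int:
        return self.L.shape[0]

    @property
    def n_components(self) -> int:
        return self.L.shape[1]

    @property
    def n_sources(self) -> int:
        return self.L.shape[1] // self.components_per_source

    def save(self, path) -> None:
        payload = {
            "L": self.L.tolist(),
            "components_per_source": self.components_per_source,
            "sensor_labels": self.sensor_labels,
            "source_labels": self.source_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ForwardModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.asarray(payload["L"], dtype=float),
            payload.get("components_per_source", 1),
            payload.get("sensor_labels", []),
            payload.get("source_labels", []),
        )


@dataclass
class NoiseModel:
    """Diagonal sensor-noise covariance (per-channel variances)."""

    variances: np.ndarray
    flagged_channels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=float)
        if self.variances.ndim != 1 or np.any(self.variances <= 0):
            raise ValueError("noise variances must be a strictly positive vector")


@dataclass
class InverseOperator:
    """Linear inverse ``K`` (source components x sensors) with its lambda2."""

    K: np.ndarray
    lambda2: float

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")


@dataclass
class ROIDefinition:
    """Map from ROI name to the member source indices in the forward model."""

    rois: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for name, idx in self.rois.items():
            if len(idx) == 0:
                raise ValueError(f"ROI {name!r} is empty")
            for i in idx:
                if i in seen:
                    warnings.warn(
                        f"source {i} belongs to both {seen[i]!r} and {name!r}",
                        stacklevel=2,
                    )
                seen[i] = name

    @property
    def roi_names(self) -> list[str]:
        return list(self.rois.keys())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(map(int, v)) for k, v in self.rois.items()}, fh)

    @classmethod
    def load(cls, path) -> "ROIDefinition":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass
class ROITimeseries:
    """One real-valued sequence per ROI (n_rois x samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.roi_names):
            raise ValueError("row count does not match ROI names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite ROI timeseries")


def estimate_noise_covariance(recording: SensorRecording) -> NoiseModel:
    """Per-channel sample variances (the diagonal noise model).

    A channel with zero variance (flatlined) gets the smallest positive
    variance found on any other channel, and is flagged.
    """
    data = recording.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    var = data.var(axis=1, ddof=1)
    flagged = list(np.flatnonzero(var == 0))
    if len(flagged) == data.shape[0]:
        raise ValueError("all channels are constant; no noise estimate possible")
    if flagged:
        floor = var[var > 0].min()
        var = var.copy()
        var[var == 0] = floor
        warnings.warn(
            f"{len(flagged)} constant channel(s) replaced by variance floor",
            stacklevel=2,
        )
    return NoiseModel(var, flagged)


def compute_inverse_operator(
    fm: ForwardModel, noise: NoiseModel, lambda2: float = 1.0 / 9.0
) -> InverseOperator:
    """Regularized minimum-norm inverse with diagonal whitening."""
    if lambda2 <= 0:
        raise ValueError("lambda2 must be positive")
    if noise.variances.shape[0] != fm.n_sensors:
        raise ValueError("noise model does not match sensor count")
    w = 1.0 / np.sqrt(noise.variances)  # diagonal whitener
    g = fm.L * w[:, None]
    gram = g @ g.T
    gram[np.diag_indices_from(gram)] += lambda2
    # solve (G G' + lambda2 I) Z = G, then K = Z' W
    z = np.linalg.solve(gram, g)
    k = z.T * w[None, :]
    return InverseOperator(k, lambda2)


def apply_inverse(inv: InverseOperator, recording: SensorRecording) -> np.ndarray:
    """Project a recording to source space: S = K X."""
    if recording.n_channels != inv.K.shape[1]:
        raise ValueError(
            f"recording has {recording.n_channels} channels, operator expects "
            f"{inv.K.shape[1]}"
        )
    return inv.K @ recording.data


def _first_pc(block: np.ndarray) -> np.ndarray:
    """First principal component timeseries of a components x samples block,
    sign-fixed so it correlates positively with the largest-variance row."""
    centered = block - block.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc = s[0] * vt[0]
    ref = centered[np.argmax(centered.var(axis=1))]
    if np.dot(pc, ref) < 0:
        pc = -pc
    return pc


def extract_roi_timeseries(
    source_data: np.ndarray,
    rois: ROIDefinition,
    fm: ForwardModel,
    fs: float,
) -> ROITimeseries:
    """Collapse source components to one timeseries per ROI.

    Per source: 3-component blocks are reduced to their first principal
    component (phase-preserving).  Per ROI: member source timeseries are
    sign-aligned to the ROI's own first principal component and averaged,
    so anti-phase members reinforce instead of cancelling.
    """
    source_data = np.asarray(source_data, dtype=float)
    cps = fm.components_per_source
    n_sources = fm.n_sources
    if source_data.shape[0] != fm.n_components:
        raise ValueError("source matrix row count does not match forward model")

    per_source = np.empty((n_sources, source_data.shape[1]))
    for s in range(n_sources):
        block = source_data[s * cps : (s + 1) * cps]
        per_source[s] = block[0] if cps == 1 else _first_pc(block)

    out = np.empty((len(rois.roi_names), source_data.shape[1]))
    for r, name in enumerate(rois.roi_names):
        idx = np.asarray(list(rois.rois[name]), dtype=int)
        if idx.min() < 0 or idx.max() >= n_sources:
            raise IndexError(f"ROI {name!r} references sources outside the model")
        members = per_source[idx]
        if len(idx) == 1:
            out[r] = members[0]
            continue
        ref = _first_pc(members)
        signs = np.sign(members @ ref)
        signs[signs == 0] = 1.0
        out[r] = (members * signs[:, None]).mean(axis=0)
    return ROITimeseries(out, fs, list(rois.roi_names))
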