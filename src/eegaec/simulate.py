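"""Synthetic EEG cohorts with known, planted envelope coupling.

The generator emulates the structure of a two-group resting-state study:
per subject, each ROI source is a sum over frequency bands of band-limited
Gaussian carriers whose amplitudes are modulated by *slow* shared
modulators,

    x_i(t) = sum_b (1 + depth * e_i^b(t)) * c_i^b(t),

where the carriers ``c_i^b`` are independent white noise band-passed to
band ``b`` and the modulators ``e_i^b`` are white noise low-passed at
``modulator_cutoff`` (default 1 Hz), standardized, and correlated across
ROIs according to the planted coupling specification.  Amplitude-envelope
correlation (AEC) measures exactly this kind of envelope co-variation, so
the planted modulator correlation ``rho`` is the coupling dial; the ground
truth AEC is *measured* on the noiseless sources by a direct envelope
correlation (the oracle), never assumed equal to ``rho``.

Sources are projected to sensors through a toy lead field (linear mixing —
the stand-in for volume conduction) plus white sensor noise at a chosen
power SNR.  Group membership only changes the coupling specification; a
clinical covariate ("number of depressive episodes") is generated from the
patients' own ground-truth AEC at a target (pair, band) cell through a
negative linear-plus-noise model, mimicking a strong negative
coupling-severity association.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .core import (
    DEFAULT_BANDS,
    DEFAULT_ROI_NAMES,
    BandDefinition,
    SensorRecording,
    roi_pairs,
)
from .inverse import ForwardModel

#: Planted group difference: controls couple sgACC_L-DLPFC_R strongly in
#: beta-1, patients weakly.  Everything else is uncoupled.
TARGET_PAIR: tuple[str, str] = ("DLPFC_R", "sgACC_L")
TARGET_BAND: str = "beta1"

CouplingSpec = Mapping[tuple[tuple[str, str], str], float]

DEFAULT_COUPLING: dict[str, dict[tuple[tuple[str, str], str], float]] = {
    "control": {(TARGET_PAIR, TARGET_BAND): 0.7},
    "patient": {(TARGET_PAIR, TARGET_BAND): 0.2},
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_per_group: int = 20
    fs: float = 512.0
    duration: float = 360.0
    n_sensors: int = 128
    n_rois: int = 4
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    coupling_spec: Mapping[str, CouplingSpec] = field(
        default_factory=lambda: DEFAULT_COUPLING
    )
    modulator_cutoff: float = 1.0
    modulation_depth: float = 0.5
    sensor_snr: float = 5.0
    covariate_intercept: float = 10.0
    covariate_slope: float = -25.0
    covariate_noise_sd: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        top = max(b.high_hz for b in self.bands)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} cannot resolve the {top} Hz band edge (need fs > {2 * top})"
            )
        if self.duration * self.fs < 2**12:
            raise ValueError("recording too short (need >= 4096 samples)")
        if not (0 < self.modulation_depth < 1):
            raise ValueError("modulation_depth must lie in (0, 1)")
        if self.sensor_snr <= 0:
            raise ValueError("sensor_snr must be positive")
        band_names = {b.name for b in self.bands}
        for group, spec in self.coupling_spec.items():
            for (pair, band), rho in spec.items():
                if not (0.0 <= rho <= 1.0):
                    raise ValueError(f"rho for {group}:{pair}:{band} outside [0, 1]")
                if band not in band_names:
                    raise ValueError(f"coupling references unknown band {band!r}")

    @property
    def roi_names(self) -> tuple[str, ...]:
        if self.n_rois == len(DEFAULT_ROI_NAMES):
            return DEFAULT_ROI_NAMES
        return tuple(f"ROI{i + 1}" for i in range(self.n_rois))


@dataclass
class SyntheticCohort:
    """Recordings plus everything the generator knows to be true."""

    recordings: list[SensorRecording]
    ground_truth_sources: list[np.ndarray]
    true_aec: np.ndarray  # subjects x pairs x bands
    labels: np.ndarray  # 0 = control, 1 = patient
    covariates: pd.DataFrame
    pair_labels: list[tuple[str, str]]
    band_labels: list[str]
    forward: ForwardModel
    config: SimulationConfig

    def __post_init__(self) -> None:
        n = len(self.recordings)
        if not (
            len(self.ground_truth_sources) == n
            and self.true_aec.shape[0] == n
            and self.labels.shape[0] == n
            and len(self.covariates) == n
        ):
            raise ValueError("cohort fields have inconsistent lengths")
        if np.any(np.abs(self.true_aec) > 1):
            raise ValueError("true_aec outside [-1, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_carriers(
    n_rois: int, n: int, band: BandDefinition, fs: float, rng: np.random.Generator
) -> np.ndarray:
    band.validate_for_fs(fs)
    sos = scipy.signal.butter(
        4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    white = rng.standard_normal((n_rois, n))
    return _standardize_rows(scipy.signal.sosfiltfilt(sos, white, axis=-1))


def _slow_modulators(
    shape: tuple[int, ...], cutoff: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    sos = scipy.signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    white = rng.standard_normal(shape)
    return _standardize_rows(scipy.signal.sosfiltfilt(sos, white, axis=-1))


def _clip_modulators(e: np.ndarray, depth: float) -> np.ndarray:
    # keep 1 + depth*e above 0.05 so the envelope never flips the carrier
    return np.maximum(e, (0.05 - 1.0) / depth)


def simulate_coupled_sources(
    band: BandDefinition,
    rho: float,
    duration: float,
    fs: float,
    depth: float = 0.5,
    seed: int = 0,
    n_rois: int = 4,
    modulator_cutoff: float = 1.0,
) -> np.ndarray:
    """ROI sources with a common planted envelope coupling ``rho``.

    All ROI pairs share the same modulator correlation, built from a shared
    factor: e_i = sqrt(rho) g0 + sqrt(1 - rho) g_i.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    band.validate_for_fs(fs)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    carriers = _band_carriers(n_rois, n, band, fs, rng)
    g = _slow_modulators((n_rois + 1, n), modulator_cutoff, fs, rng)
    e = np.sqrt(rho) * g[0] + np.sqrt(1.0 - rho) * g[1:]
    e = _clip_modulators(e, depth) if depth > 0 else e
    return (1.0 + depth * e) * carriers


def _modulator_correlation_matrix(
    spec: CouplingSpec, band: str, roi_names: Sequence[str]
) -> np.ndarray:
    """Target correlation matrix of the slow modulators for one band."""
    names = list(roi_names)
    r = np.eye(len(names))
    for (pair, b), rho in spec.items():
        if b != band:
            continue
        i, j = names.index(pair[0]), names.index(pair[1])
        r[i, j] = r[j, i] = rho
    # project to the nearest positive-definite correlation matrix
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-8:
        w = np.maximum(w, 1e-8)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def simulate_subject_sources(
    config: SimulationConfig, spec: CouplingSpec, seed
) -> np.ndarray:
    """Broadband ROI sources (n_rois x samples) for one subject."""
    rng = np.random.default_rng(seed)
    n = int(round(config.duration * config.fs))
    total = np.zeros((config.n_rois, n))
    for band in config.bands:
        carriers = _band_carriers(config.n_rois, n, band, config.fs, rng)
        r = _modulator_correlation_matrix(spec, band.name, config.roi_names)
        g = _slow_modulators(
            (config.n_rois, n), config.modulator_cutoff, config.fs, rng
        )
        e = np.linalg.cholesky(r) @ g
        e = _clip_modulators(e, config.modulation_depth)
        total += (1.0 + config.modulation_depth * e) * carriers
    return total


def envelope_correlation_oracle(
    sources: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition],
    trim_s: float = 1.0,
) -> np.ndarray:
    """Ground-truth AEC: direct envelope correlation on noiseless sources.

    Band-pass each source, take the Hilbert envelope, drop ``trim_s``
    seconds at each end and Pearson-correlate per pair.  No mixing, no
    inverse, no orthogonalization — this is the quantity the pipeline is
    supposed to recover, measured where nothing can leak.
    """
    sources = np.asarray(sources, dtype=float)
    n_rois, n = sources.shape
    trim = int(round(trim_s * fs))
    pairs = list(itertools.combinations(range(n_rois), 2))
    out = np.empty((len(pairs), len(bands)))
    for b, band in enumerate(bands):
        sos = scipy.signal.butter(
            4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
        )
        filt = scipy.signal.sosfiltfilt(sos, sources, axis=-1)
        env = np.abs(scipy.signal.hilbert(filt, axis=-1))[:, trim : n - trim]
        c = np.corrcoef(env)
        for p, (i, j) in enumerate(pairs):
            out[p, b] = c[i, j]
    return out


def make_toy_leadfield(
    n_sensors: int,
    n_source_components: int,
    smoothness: float = 2.0,
    seed: int = 0,
    identity: bool = False,
) -> ForwardModel:
    """Random smooth full-rank lead field with condition number < 100.

    Columns are spatially smoothed Gaussian random topographies (adjacent
    sensors see correlated projections, as volume conduction produces),
    unit-normalized.  ``identity=True`` returns a square identity matrix
    for pipeline self-tests.
    """
    if identity:
        if n_sensors != n_source_components:
            raise ValueError("identity lead field requires a square shape")
        return ForwardModel(np.eye(n_sensors))
    if n_sensors < n_source_components:
        raise ValueError("cannot build a full-column-rank lead field: too few sensors")
    rng = np.random.default_rng(seed)
    l = rng.standard_normal((n_sensors, n_source_components))
    if smoothness > 0:
        half = int(np.ceil(3 * smoothness))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / smoothness) ** 2)
        kern /= kern.sum()
        l = np.apply_along_axis(
            lambda c: np.convolve(np.pad(c, half, mode="edge"), kern, mode="same")[
                half:-half
            ],
            0,
            l,
        )
    for _ in range(10):
        l /= np.linalg.norm(l, axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(l, full_matrices=False)
        if s[-1] > s[0] / 100:
            break
        s = np.maximum(s, s[0] / 90.0)
        l = (u * s) @ vt
    l /= np.linalg.norm(l, axis=0, keepdims=True)
    if np.linalg.cond(l) >= 100:
        raise RuntimeError("could not condition the toy lead field")
    return ForwardModel(l)


def mix_to_sensors(
    sources: np.ndarray,
    fm: ForwardModel,
    snr: float,
    seed: int = 0,
    fs: float = 512.0,
) -> SensorRecording:
    """Project sources through the lead field and add white sensor noise.

    ``snr`` is the power ratio of the projected signal to the added noise;
    ``np.inf`` disables the noise entirely.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.shape[0] != fm.n_components:
        raise ValueError(
            f"{sources.shape[0]} source rows vs {fm.n_components} lead-field columns"
        )
    if not snr > 0:
        raise ValueError("snr must be positive")
    signal = fm.L @ sources
    if np.isinf(snr):
        noisy = signal
    else:
        rng = np.random.default_rng(seed)
        sig_power = np.mean(signal**2)
        noise = rng.standard_normal(signal.shape)
        noise *= np.sqrt(sig_power / snr / np.mean(noise**2))
        noisy = signal + noise
    return SensorRecording(
        noisy, fs, meta={"snr": float(snr), "seed": int(seed), "fs": float(fs)}
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Two groups differing only in their planted coupling.

    All randomness derives deterministically from ``config.seed``; the same
    configuration reproduces the cohort bit for bit.
    """
    roi_names = config.roi_names
    pair_labels = roi_pairs(roi_names)
    band_labels = [b.name for b in config.bands]
    groups = list(config.coupling_spec.keys())
    if len(groups) != 2:
        raise ValueError("coupling_spec must define exactly two groups")

    root = np.random.SeedSequence(config.seed)
    lf_seed, cov_seed = root.spawn(2)
    fm = make_toy_leadfield(
        config.n_sensors,
        config.n_rois,
        seed=int(lf_seed.generate_state(1)[0] % 2**31),
    )

    recordings, sources_list = [], []
    n_total = 2 * config.n_per_group
    true_aec = np.empty((n_total, len(pair_labels), len(band_labels)))
    labels = np.empty(n_total, dtype=int)
    subj_seeds = root.spawn(n_total)
    s = 0
    for g, group in enumerate(groups):
        spec = config.coupling_spec[group]
        for _ in range(config.n_per_group):
            src_seed, noise_seed = subj_seeds[s].spawn(2)
            src = simulate_subject_sources(config, spec, src_seed)
            rec = mix_to_sensors(
                src,
                fm,
                config.sensor_snr,
                seed=int(noise_seed.generate_state(1)[0] % 2**31),
                fs=config.fs,
            )
            true_aec[s] = envelope_correlation_oracle(src, config.fs, config.bands)
            labels[s] = g
            recordings.append(rec)
            sources_list.append(src)
            s += 1

    covariates = _make_covariates(
        config, labels, true_aec, pair_labels, band_labels, cov_seed
    )
    return SyntheticCohort(
        recordings,
        sources_list,
        true_aec,
        labels,
        covariates,
        pair_labels,
        band_labels,
        fm,
        config,
    )


def _make_covariates(
    config: SimulationConfig,
    labels: np.ndarray,
    true_aec: np.ndarray,
    pair_labels: list[tuple[str, str]],
    band_labels: list[str],
    seed,
) -> pd.DataFrame:
    """Demographics plus the planted episodes-AEC association.

    Episodes counts for patients follow
    ``round(max(1, a + slope * AEC_target + noise))`` with a negative
    default slope, so low connectivity at the target cell means many
    lifetime episodes.  Controls have zero episodes by construction.
    """
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    patient = labels == 1
    age = np.clip(np.round(rng.normal(39, 13.5, n)), 18, 70).astype(int)
    sex = np.where(rng.random(n) < 0.7, "F", "M")
    education = rng.choice(["HS", "BA", "MA"], size=n, p=[0.3, 0.45, 0.25])
    severity = np.where(
        patient,
        np.clip(np.round(rng.normal(33, 11, n), 1), 14, 63),
        np.clip(np.round(rng.normal(1.5, 3.0, n), 1), 0, 13),
    )
    try:
        p_ix = pair_labels.index(tuple(sorted(TARGET_PAIR)))
        b_ix = band_labels.index(TARGET_BAND)
        target_aec = true_aec[:, p_ix, b_ix]
    except ValueError:
        target_aec = true_aec[:, 0, 0]
    raw = (
        config.covariate_intercept
        + config.covariate_slope * target_aec
        + rng.normal(0, config.covariate_noise_sd, n)
    )
    episodes = np.where(patient, np.round(np.maximum(1, raw)), 0).astype(int)
    onset = np.where(
        patient, np.maximum(16, age - np.round(rng.uniform(1, 15, n))), np.nan
    )
    weeks = np.where(patient, np.round(rng.lognormal(2.5, 0.6, n)), np.nan)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": np.where(patient, "patient", "control"),
            "age": age,
            "sex": sex,
            "education": education,
            "severity": severity,
            "episodes": episodes,
            "onset_age": onset,
            "episode_weeks": weeks,
        }
    )


def export_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write recordings as EDF, covariates as CSV, ground truth as JSON."""
    from pathlib import Path

    from .edf import write_edf

    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec, sid in zip(cohort.recordings, cohort.covariates["subject_id"]):
        write_edf(rec_dir / f"{sid}.edf", rec)
    cohort.covariates.to_csv(out / "cohort.csv", index=False)
    cohort.forward.save(out / "leadfield.json")
    rois = {name: [i] for i, name in enumerate(cohort.config.roi_names)}
    with open(out / "rois.json", "w") as fh:
        json.dump(rois, fh)
    spec_json = {
        group: {f"{a}|{b}|{band}": rho for ((a, b), band), rho in spec.items()}
        for group, spec in cohort.config.coupling_spec.items()
    }
    truth = {
        "seed": cohort.config.seed,
        "coupling_spec": spec_json,
        "pair_labels": [list(p) for p in cohort.pair_labels],
        "band_labels": cohort.band_labels,
        "true_aec": cohort.true_aec.tolist(),
        "labels": cohort.labels.tolist(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
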