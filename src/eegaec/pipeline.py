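"""End-to-end orchestration: simulate/load -> connectivity -> statistics.

A :class:`RunConfig` (usually loaded from YAML) describes either a
synthetic study or a directory of EDF recordings plus lead field, ROI
definitions and cohort table.  :func:`run_pipeline` chains the stages —
source reconstruction and orthogonalized AEC per subject, permutation
group contrast with BH-FDR, clinical permutation correlations with an
ANCOVA-style adjusted model, and the leave-one-out SVM — writing TSV/JSON
outputs whose numeric content is fully reproducible from the master seed.

All files are written atomically (temp file then rename) and every output
records the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .classify import ClassifierConfig, classification_metrics, features_from_tensor, loocv_svm
from .clinical import clinical_correlations, linear_model_f
from .connectivity import ConnectivityTensor, cohort_connectivity
from .core import DEFAULT_BANDS, BandDefinition
from .edf import read_recording
from .group_stats import PermutationConfig, group_contrast
from .inverse import ForwardModel, ROIDefinition
from .simulate import (
    DEFAULT_COUPLING,
    TARGET_BAND,
    TARGET_PAIR,
    SimulationConfig,
    simulate_cohort,
)


class BandSpec(BaseModel):
    name: str
    low_hz: float
    high_hz: float


class SimulateSection(BaseModel):
    n_per_group: int = 20
    fs: float = 512.0
    duration: float = 360.0
    n_sensors: int = 128
    sensor_snr: float = 5.0
    modulation_depth: float = 0.5
    control_rho: float = 0.7
    patient_rho: float = 0.2
    target_pair: tuple[str, str] = TARGET_PAIR
    target_band: str = TARGET_BAND
    export_recordings: bool = False


class PathsSection(BaseModel):
    recordings_dir: str
    leadfield: str
    rois: str
    cohort_csv: str


class AnalysisSection(BaseModel):
    orthogonalize: bool = True
    window_s: Optional[float] = None
    lambda2: float = Field(default=1.0 / 9.0, gt=0)
    n_perm: int = Field(default=10000, ge=100)
    q: float = Field(default=0.05, gt=0, lt=1)
    highpass_hz: Optional[float] = None
    notch_hz: Optional[float] = None


class ClassifierSection(BaseModel):
    box_constraint: float = Field(default=3.0, gt=0)
    kernel_scale: float = Field(default=1.0, gt=0)
    standardize: bool = False
    band: str = "beta1"


class ClinicalSection(BaseModel):
    target_pair: tuple[str, str] = TARGET_PAIR
    target_band: str = TARGET_BAND
    covariate_columns: list[str] = Field(
        default_factory=lambda: ["onset_age", "episodes", "episode_weeks"]
    )
    adjust_for: list[str] = Field(
        default_factory=lambda: ["age", "sex", "education", "severity"]
    )


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-friendly)."""

    out_dir: str
    seed: int = 0
    simulate: Optional[SimulateSection] = None
    paths: Optional[PathsSection] = None
    bands: Optional[list[BandSpec]] = None
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    classifier: ClassifierSection = Field(default_factory=ClassifierSection)
    clinical: ClinicalSection = Field(default_factory=ClinicalSection)
    group_column: str = "group"
    control_label: str = "control"
    patient_label: str = "patient"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.simulate is None) == (self.paths is None):
            raise ValueError("exactly one of 'simulate' or 'paths' must be given")
        return self

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        if self.bands is None:
            return DEFAULT_BANDS
        return tuple(BandDefinition(b.name, b.low_hz, b.high_hz) for b in self.bands)

    def config_hash(self) -> str:
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.10g")


def _json_text(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n"


def simulation_config_from_run(cfg: RunConfig) -> SimulationConfig:
    sim = cfg.simulate
    pair = tuple(sorted(sim.target_pair))
    coupling = {
        "control": {(pair, sim.target_band): sim.control_rho},
        "patient": {(pair, sim.target_band): sim.patient_rho},
    }
    return SimulationConfig(
        n_per_group=sim.n_per_group,
        fs=sim.fs,
        duration=sim.duration,
        n_sensors=sim.n_sensors,
        bands=cfg.band_definitions(),
        coupling_spec=coupling,
        modulation_depth=sim.modulation_depth,
        sensor_snr=sim.sensor_snr,
        seed=cfg.seed,
    )


def _load_real_inputs(cfg: RunConfig):
    paths = cfg.paths
    fm = ForwardModel.load(paths.leadfield)
    rois = ROIDefinition.load(paths.rois)
    covariates = pd.read_csv(paths.cohort_csv)
    recordings = []
    for sid in covariates["subject_id"]:
        rec = read_recording(
            Path(paths.recordings_dir) / f"{sid}.edf",
            highpass_hz=cfg.analysis.highpass_hz,
            notch_hz=cfg.analysis.notch_hz,
        )
        recordings.append(rec)
    return recordings, fm, rois, covariates


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a report bundle (also on disk)."""
    out = Path(cfg.out_dir)
    chash = cfg.config_hash()
    report: dict = {"config_hash": chash, "seed": cfg.seed, "version": __version__}

    stage = "input"
    try:
        if cfg.simulate is not None:
            sim_cfg = simulation_config_from_run(cfg)
            cohort = simulate_cohort(sim_cfg)
            recordings = cohort.recordings
            fm = cohort.forward
            rois = ROIDefinition(
                {name: [i] for i, name in enumerate(sim_cfg.roi_names)}
            )
            covariates = cohort.covariates
            if cfg.simulate.export_recordings:
                from .simulate import export_cohort

                export_cohort(cohort, out / "cohort")
        else:
            recordings, fm, rois, covariates = _load_real_inputs(cfg)

        stage = "connectivity"
        tensor = cohort_connectivity(
            recordings,
            fm,
            rois,
            cfg.band_definitions(),
            lambda2=cfg.analysis.lambda2,
            orthogonalize=cfg.analysis.orthogonalize,
            window_s=cfg.analysis.window_s,
            subject_ids=list(covariates["subject_id"].astype(str)),
        )
        conn_df = tensor.to_frame()
        _atomic_write(out / "connectivity.tsv", _tsv(conn_df))
        _atomic_write(
            out / "connectivity.json",
            _json_text(
                {"config_hash": chash, "seed": cfg.seed, "meta": tensor.meta}
            ),
        )

        stage = "group_stats"
        groups = covariates[cfg.group_column].astype(str).to_numpy()
        is_control = groups == cfg.control_label
        is_patient = groups == cfg.patient_label
        tensor_a = ConnectivityTensor(
            tensor.values[is_control],
            [s for s, m in zip(tensor.subject_ids, is_control) if m],
            tensor.pair_labels,
            tensor.band_labels,
        )
        tensor_b = ConnectivityTensor(
            tensor.values[is_patient],
            [s for s, m in zip(tensor.subject_ids, is_patient) if m],
            tensor.pair_labels,
            tensor.band_labels,
        )
        statmap = group_contrast(
            tensor_a,
            tensor_b,
            PermutationConfig(n_perm=cfg.analysis.n_perm, seed=cfg.seed + 1),
            q=cfg.analysis.q,
        )
        _atomic_write(out / "group_stats.tsv", _tsv(statmap.table))
        group_summary = {
            "config_hash": chash,
            "m": statmap.m,
            "q": statmap.q,
            "fdr_threshold": statmap.fdr_threshold,
            "n_perm": statmap.n_perm,
            "seed": statmap.seed,
            "sign_convention": "t > 0 means controls > patients",
        }
        _atomic_write(out / "group_stats.json", _json_text(group_summary))
        report["group_stats"] = group_summary

        stage = "clinical"
        pa, pb = cfg.clinical.target_pair
        target_vals = tensor.cell(pa, pb, cfg.clinical.target_band)
        pat_cov = covariates[is_patient].reset_index(drop=True)
        n_pat = int(is_patient.sum())
        if n_pat >= 4:
            corr = clinical_correlations(
                target_vals[is_patient],
                pat_cov,
                cfg.clinical.covariate_columns,
                n_perm=cfg.analysis.n_perm,
                seed=cfg.seed + 2,
                q=cfg.analysis.q,
            )
            fdr_thr = corr.attrs["fdr_threshold"]
        else:
            # too few patients for a meaningful correlation: report NaNs
            corr = pd.DataFrame(
                {
                    "covariate": cfg.clinical.covariate_columns,
                    "n": n_pat,
                    "r": np.nan,
                    "p": np.nan,
                    "fdr_reject": False,
                }
            )
            fdr_thr = 0.0
        design = pat_cov[cfg.clinical.adjust_for].copy()
        design.insert(0, "aec", target_vals[is_patient])
        k_predictors = pd.get_dummies(design, drop_first=True).shape[1]
        if n_pat > k_predictors + 1:
            ancova = linear_model_f(
                pd.to_numeric(pat_cov["episodes"], errors="coerce").to_numpy(float),
                design,
            )
            ancova_summary = {
                "f": ancova.f,
                "df1": ancova.df1,
                "df2": ancova.df2,
                "p": ancova.p,
                "overflow": ancova.overflow,
            }
        else:
            ancova_summary = {"skipped": f"n={n_pat} too small for the model"}
        _atomic_write(out / "clinical.tsv", _tsv(corr))
        clinical_summary = {
            "config_hash": chash,
            "target_pair": list(cfg.clinical.target_pair),
            "target_band": cfg.clinical.target_band,
            "n_patients": n_pat,
            "fdr_threshold": fdr_thr,
            "ancova": ancova_summary,
        }
        _atomic_write(out / "clinical.json", _json_text(clinical_summary))
        report["clinical"] = clinical_summary

        stage = "classifier"
        feats = features_from_tensor(tensor, band=cfg.classifier.band)
        labels = np.where(is_patient, 1, 0)
        preds = loocv_svm(
            feats,
            labels,
            ClassifierConfig(
                box_constraint=cfg.classifier.box_constraint,
                kernel_scale=cfg.classifier.kernel_scale,
                standardize=cfg.classifier.standardize,
            ),
        )
        sens, spec, acc = classification_metrics(preds, labels, positive_class=1)
        clf_summary = {
            "config_hash": chash,
            "band": cfg.classifier.band,
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
            "n_subjects": int(labels.size),
        }
        _atomic_write(out / "classifier.json", _json_text(clf_summary))
        report["classifier"] = clf_summary

        stage = "log"
        _atomic_write(
            out / "run_log.json",
            _json_text(
                {
                    "config_hash": chash,
                    "seed": cfg.seed,
                    "version": __version__,
                    "config": json.loads(cfg.model_dump_json()),
                }
            ),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
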