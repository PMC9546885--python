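"""Orthogonalized amplitude-envelope correlation (AEC) between ROI timeseries.

The connectivity measure works per frequency band:

1. band-pass every ROI timeseries (zero-phase Butterworth, order 4);
2. optionally replace the set of band-limited signals by the *closest
   mutually orthogonal set* (symmetric, multivariate leakage correction:
   instantaneous signal shared between ROIs — the signature of volume
   conduction and inverse-solution leakage — is removed jointly, not
   pairwise);
3. take the amplitude envelope of each signal as the magnitude of its
   analytic (Hilbert) signal;
4. Pearson-correlate envelopes per ROI pair, either over the full record or
   averaged over non-overlapping windows.

One second is trimmed from each end of the envelopes before correlation to
discard filter and Hilbert edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.signal

from .core import BandDefinition, SensorRecording, roi_pairs

EDGE_TRIM_S = 1.0


def bandpass(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    band.validate_for_fs(fs)
    x = np.asarray(x, dtype=float)
    sos = scipy.signal.butter(
        4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    # sosfiltfilt needs a minimum padding length; guard short inputs early.
    min_len = 3 * (2 * 4 + 1)
    if x.shape[-1] <= min_len:
        raise ValueError(
            f"input too short for zero-phase filtering ({x.shape[-1]} samples, "
            f"need > {min_len})"
        )
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)


def lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass along the last axis."""
    sos = scipy.signal.butter(4, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _polar_orthonormal(a: np.ndarray) -> np.ndarray:
    """Orthonormal polar factor of a tall matrix (samples x n).

    Computed through the eigendecomposition of the small n x n Gram matrix,
    which is much cheaper than an SVD of the full matrix for long signals.
    Tiny eigenvalues are clamped, so near-degenerate directions yield *some*
    orthonormal frame rather than failing; rank checks happen upstream.
    """
    gram = a.T @ a
    w, v = np.linalg.eigh(gram)
    w = np.maximum(w, w[-1] * 1e-15 + np.finfo(float).tiny)
    inv_sqrt = (v * (1.0 / np.sqrt(w))) @ v.T
    return a @ inv_sqrt


def symmetric_orthogonalize(
    m: np.ndarray, tol: float = 1e-9, max_iter: int = 200, strict: bool = True
) -> np.ndarray:
    """Closest set of mutually orthogonal signals to the rows of ``m``.

    Finds the matrix with pairwise-orthogonal rows minimizing the Frobenius
    distance to ``m`` by alternating (a) the orthonormal polar factor of the
    column-scaled matrix and (b) per-row least-squares rescaling to the
    original rows.  All rows are corrected jointly and no row is privileged
    — the correction is symmetric in the ROIs.

    Parameters
    ----------
    m : array, shape (n_signals, n_samples)
        Full-row-rank input; ``n_signals >= 2``.

    Raises
    ------
    ValueError
        If ``strict`` (the default) and the rows are linearly dependent
        (e.g. one ROI timeseries is an exact copy or linear combination of
        others): such a set has no unique closest orthogonal counterpart
        and the offending dependency is named.  With ``strict=False`` the
        limiting solution is returned instead, in which a fully dependent
        row collapses to (numerically) zero — its instantaneous content is
        entirely shared, so nothing of it survives the correction.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 signals")
    n, t = m.shape
    if t < n:
        raise ValueError("need at least as many samples as signals")
    svals = np.linalg.svd(m, compute_uv=False)
    if strict and svals[-1] <= svals[0] * 1e-10:
        # identify which row is (nearly) a linear combination of the others
        offender = _find_dependent_row(m)
        raise ValueError(
            f"rank-deficient input: row {offender} is linearly dependent on "
            "the other signals; symmetric orthogonalization is undefined"
        )

    a = m.T  # samples x n
    d = np.linalg.norm(m, axis=1)  # initial row magnitudes
    prev_err = np.inf
    o = None
    for _ in range(max_iter):
        p = _polar_orthonormal(a * d)
        d = np.einsum("ij,ij->j", a, p)
        o = p * d
        err = np.linalg.norm(a - o)
        if abs(prev_err - err) <= tol * max(err, 1.0):
            break
        prev_err = err
    return o.T


def _find_dependent_row(m: np.ndarray) -> int:
    n = m.shape[0]
    for i in range(n):
        rest = np.delete(m, i, axis=0)
        resid = m[i] - rest.T @ np.linalg.lstsq(rest.T, m[i], rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(m[i]), 1.0):
            return i
    return n - 1


def _independent_rows(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy screen: flag rows that add no direction beyond earlier rows."""
    keep = np.zeros(m.shape[0], dtype=bool)
    basis: list[np.ndarray] = []
    for i, row in enumerate(m):
        resid = row.copy()
        for b in basis:
            resid -= (resid @ b) * b
        if np.linalg.norm(resid) > tol * max(np.linalg.norm(row), 1.0):
            keep[i] = True
            basis.append(resid / np.linalg.norm(resid))
    return keep


def _leakage_correct(filt: np.ndarray) -> np.ndarray:
    """Symmetric orthogonalization as used inside the AEC pipeline.

    Rows are normalized to unit power first: the closest-orthogonal fit
    weights rows by magnitude, and reconstructed ROI amplitudes are
    arbitrary (depth- and regularization-dependent), so no ROI should
    dominate the correction — this also makes AEC exactly invariant to
    per-row rescaling.  A row that is numerically a linear combination of
    the others is entirely shared (leaked) signal: it is zeroed, and its
    AEC with everything is 0 by convention.
    """
    norms = np.linalg.norm(filt, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normed = filt / norms
    keep = _independent_rows(normed)
    out = np.zeros_like(normed)
    if keep.sum() >= 2:
        out[keep] = symmetric_orthogonalize(normed[keep], strict=False)
    elif keep.sum() == 1:
        out[keep] = normed[keep]
    return out


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal, |x + i*H(x)|, along the last axis."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    n = x.shape[-1]
    nfft = scipy.fft.next_fast_len(n)
    analytic = scipy.signal.hilbert(x, N=nfft, axis=-1)[..., :n]
    return np.abs(analytic)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI AEC matrix for one band of one subject."""

    values: np.ndarray
    band: str
    roi_names: Sequence[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.roi_names):
            raise ValueError("connectivity matrix shape does not match ROI list")
        self.values = v

    def pair_value(self, roi_a: str, roi_b: str) -> float:
        i = list(self.roi_names).index(roi_a)
        j = list(self.roi_names).index(roi_b)
        return float(self.values[i, j])


@dataclass
class ConnectivityTensor:
    """Subjects x ROI-pairs x bands array of AEC values.

    Pair ordering is the fixed lexicographic order over ROI names; band
    ordering follows the band list used to compute the tensor.
    """

    values: np.ndarray
    subject_ids: list[str]
    pair_labels: list[tuple[str, str]]
    band_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expect = (len(self.subject_ids), len(self.pair_labels), len(self.band_labels))
        if v.shape != expect:
            raise ValueError(f"tensor shape {v.shape} != labels {expect}")
        self.values = v

    def cell(self, roi_a: str, roi_b: str, band: str) -> np.ndarray:
        """All subjects' AEC for one (pair, band) cell."""
        key = tuple(sorted((roi_a, roi_b)))
        p = self.pair_labels.index(key)
        b = self.band_labels.index(band)
        return self.values[:, p, b]

    def to_frame(self):
        """Long-format DataFrame: subject_id, roi_a, roi_b, band, aec."""
        import pandas as pd

        rows = []
        for s, sid in enumerate(self.subject_ids):
            for p, (ra, rb) in enumerate(self.pair_labels):
                for b, band in enumerate(self.band_labels):
                    rows.append((sid, ra, rb, band, self.values[s, p, b]))
        return pd.DataFrame(
            rows, columns=["subject_id", "roi_a", "roi_b", "band", "aec"]
        )

    @classmethod
    def from_frame(cls, df) -> "ConnectivityTensor":
        subject_ids = list(dict.fromkeys(df["subject_id"].astype(str)))
        pair_labels = sorted(
            {tuple(sorted((a, b))) for a, b in zip(df["roi_a"], df["roi_b"])}
        )
        band_labels = list(dict.fromkeys(df["band"]))
        values = np.full((len(subject_ids), len(pair_labels), len(band_labels)), np.nan)
        s_ix = {s: i for i, s in enumerate(subject_ids)}
        p_ix = {p: i for i, p in enumerate(pair_labels)}
        b_ix = {b: i for i, b in enumerate(band_labels)}
        for row in df.itertuples(index=False):
            key = tuple(sorted((row.roi_a, row.roi_b)))
            values[s_ix[str(row.subject_id)], p_ix[key], b_ix[row.band]] = row.aec
        if np.isnan(values).any():
            raise ValueError("long-format table does not cover every cell")
        return cls(values, subject_ids, pair_labels, band_labels)


def _pearson_rows(e: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the rows of ``e``.

    A row with (numerically) no variance — an envelope whose signal was
    entirely removed as leakage — correlates 0 with everything: there is no
    residual envelope co-variation to report.
    """
    e = e - e.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(e, axis=1)
    dead = norms <= norms.max() * 1e-9 if norms.max() > 0 else norms == 0
    safe = np.where(dead, 1.0, norms)
    c = (e @ e.T) / np.outer(safe, safe)
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    return np.clip(c, -1.0, 1.0)


def aec(
    roi_data: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition],
    roi_names: Sequence[str],
    orthogonalize: bool = True,
    window_s: float | None = None,
    subject_id: str = "",
) -> list[ConnectivityMatrix]:
    """Amplitude-envelope correlation matrices, one per band.

    Parameters
    ----------
    roi_data : array, shape (n_rois, n_samples)
    orthogonalize : bool
        Apply the symmetric leakage correction to the band-limited signals
        before the Hilbert transform (the default, and the analysis the
        pipeline reports).
    window_s : float or None
        If set, envelopes are cut into non-overlapping windows of this
        length, each window is correlated separately, and the per-pair
        correlations are averaged.  ``None`` (default) correlates once over
        the whole record.
    """
    roi_data = np.asarray(roi_data, dtype=float)
    if roi_data.ndim != 2 or roi_data.shape[0] != len(roi_names):
        raise ValueError("roi_data must be (n_rois, n_samples) matching roi_names")
    trim = int(round(EDGE_TRIM_S * fs))
    n = roi_data.shape[1]
    for band in bands:
        min_needed = max(
            int(10 * fs / band.low_hz),
            int(4 * window_s * fs) if window_s else 0,
        )
        if n - 2 * trim < max(min_needed, 16):
            raise ValueError(
                f"record too short for band {band.name!r}: {n} samples "
                f"(need > {min_needed + 2 * trim})"
            )

    out = []
    for band in bands:
        filt = bandpass(roi_data, band, fs)
        if orthogonalize:
            filt = _leakage_correct(filt)
        env = amplitude_envelope(filt)[:, trim : n - trim]
        if window_s is None:
            corr = _pearson_rows(env)
        else:
            w = int(round(window_s * fs))
            n_win = env.shape[1] // w
            mats = [
                _pearson_rows(env[:, k * w : (k + 1) * w]) for k in range(n_win)
            ]
            corr = np.mean(mats, axis=0)
        np.fill_diagonal(corr, np.nan)
        corr = (corr + corr.T) / 2.0  # enforce exact symmetry
        out.append(
            ConnectivityMatrix(corr, band.name, list(roi_names), subject_id)
        )
    return out


def matrices_to_pairs(mats: list[ConnectivityMatrix]) -> np.ndarray:
    """Stack per-band matrices of one subject into a (pairs, bands) array."""
    roi_names = mats[0].roi_names
    pairs = roi_pairs(roi_names)
    out = np.empty((len(pairs), len(mats)))
    for b, m in enumerate(mats):
        for p, (ra, rb) in enumerate(pairs):
            out[p, b] = m.pair_value(ra, rb)
    return out


def cohort_connectivity(
    recordings: Sequence[SensorRecording],
    forward,
    rois,
    bands: Sequence[BandDefinition],
    lambda2: float = 1.0 / 9.0,
    orthogonalize: bool = True,
    window_s: float | None = None,
    subject_ids: Sequence[str] | None = None,
) -> ConnectivityTensor:
    """Full per-subject pipeline: inverse -> ROI extraction -> AEC.

    Runs the minimum-norm inverse (noise covariance estimated per subject
    from the recording itself), extracts one timeseries per ROI and computes
    orthogonalized AEC per band; stacks results into a subjects x pairs x
    bands tensor.
    """
    from . import inverse as inv_mod

    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(recordings))]
    roi_names = list(rois.roi_names)
    pair_labels = roi_pairs(roi_names)
    band_labels = [b.name for b in bands]
    values = np.empty((len(recordings), len(pair_labels), len(band_labels)))
    for s, rec in enumerate(recordings):
        try:
            noise = inv_mod.estimate_noise_covariance(rec)
            op = inv_mod.compute_inverse_operator(forward, noise, lambda2)
            src = inv_mod.apply_inverse(op, rec)
            roi_ts = inv_mod.extract_roi_timeseries(src, rois, forward, fs=rec.fs)
            mats = aec(
                roi_ts.data,
                rec.fs,
                bands,
                roi_ts.roi_names,
                orthogonalize=orthogonalize,
                window_s=window_s,
                subject_id=subject_ids[s],
            )
        except Exception as exc:
            raise RuntimeError(
                f"connectivity failed for subject {subject_ids[s]}: {exc}"
            ) from exc
        values[s] = matrices_to_pairs(mats)
    return ConnectivityTensor(
        values,
        list(subject_ids),
        pair_labels,
        band_labels,
        meta={"lambda2": lambda2, "orthogonalize": orthogonalize, "window_s": window_s},
    )
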