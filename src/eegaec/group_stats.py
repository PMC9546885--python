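"""Group contrasts: non-parametric permutation t-tests with BH-FDR control.

Each (ROI pair, band) cell of the two groups' connectivity tensors is
compared with a two-tailed permutation test built on the Welch t statistic:
the pooled values are randomly re-split into groups of the original sizes
and the observed |t| is ranked in the permutation distribution, using the
add-one Monte-Carlo estimator p = (1 + #{|t*| >= |t|}) / (1 + n_perm) so p
is never zero and remains a valid p-value.  The family of all pair x band
cells is then thresholded by the Benjamini–Hochberg step-up rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings; the test is always two-tailed."""

    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class StatMap:
    """Per-cell t, p and FDR decision, plus the family metadata."""

    table: pd.DataFrame  # columns: roi_a, roi_b, band, t, p, p_unc_lt_01, fdr_reject
    m: int
    q: float
    fdr_threshold: float
    n_perm: int
    seed: int

    def cell(self, roi_a: str, roi_b: str, band: str) -> pd.Series:
        a, b = sorted((roi_a, roi_b))
        t = self.table
        row = t[(t.roi_a == a) & (t.roi_b == b) & (t.band == band)]
        if row.empty:
            raise KeyError(f"no cell ({roi_a}, {roi_b}, {band})")
        return row.iloc[0]


def _welch_t(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) / a.shape[axis]
    vb = b.var(axis=axis, ddof=1) / b.shape[axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ma - mb) / np.sqrt(va + vb)


def _permuted_abs_t(
    pooled: np.ndarray, n1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """|Welch t| for n_perm random re-splits of the pooled sample."""
    mat = np.broadcast_to(pooled, (n_perm, pooled.shape[0])).copy()
    mat = rng.permuted(mat, axis=1)
    return np.abs(_welch_t(mat[:, :n1], mat[:, n1:], axis=1))


def permutation_t_test(
    a: np.ndarray, b: np.ndarray, cfg: PermutationConfig = PermutationConfig()
) -> tuple[float, float]:
    """Two-tailed permutation test of a group difference in means.

    Returns the observed Welch t (positive when group A's mean is larger)
    and the Monte-Carlo p-value.  Degenerate input where every pooled value
    is identical yields (0, 1) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; p = 1", stacklevel=2)
        return 0.0, 1.0
    t_obs = float(_welch_t(a, b))
    if not np.isfinite(t_obs):  # zero variance in both groups, unequal means
        t_obs = np.inf if a.mean() > b.mean() else -np.inf
    rng = np.random.default_rng(cfg.seed)
    null = _permuted_abs_t(pooled, a.size, cfg.n_perm, rng)
    null = np.where(np.isfinite(null), null, np.inf)
    p = (1.0 + np.count_nonzero(null >= abs(t_obs))) / (1.0 + cfg.n_perm)
    return t_obs, float(p)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up: reject flags and the step-up threshold.

    The threshold is k*q/m for the largest rank k with p_(k) <= k*q/m,
    or 0 when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    ok = p[order] <= ranks * q / m
    if not ok.any():
        return np.zeros(m, dtype=bool), 0.0
    k = ranks[ok][-1]
    threshold = k * q / m
    return p <= threshold, float(threshold)


def group_contrast(
    tensor_a,
    tensor_b,
    cfg: PermutationConfig = PermutationConfig(),
    q: float = 0.05,
) -> StatMap:
    """Permutation t-test per (pair, band) cell, BH-FDR over the family.

    ``tensor_a`` holds the reference group (controls): t > 0 means group A
    has the larger mean AEC.  A single permutation schedule is shared
    across cells; the uncorrected p < 0.01 mask is reported alongside the
    FDR decision.
    """
    if (
        tensor_a.pair_labels != tensor_b.pair_labels
        or tensor_a.band_labels != tensor_b.band_labels
    ):
        raise ValueError("tensors have mismatched pair/band axes")
    n1 = tensor_a.values.shape[0]
    n2 = tensor_b.values.shape[0]
    pairs, bands = tensor_a.pair_labels, tensor_a.band_labels
    pooled = np.concatenate([tensor_a.values, tensor_b.values], axis=0)
    flat = pooled.reshape(n1 + n2, -1)  # subjects x cells

    rng = np.random.default_rng(cfg.seed)
    idx = np.broadcast_to(np.arange(n1 + n2), (cfg.n_perm, n1 + n2)).copy()
    idx = rng.permuted(idx, axis=1)

    t_obs = _welch_t(flat[:n1], flat[n1:], axis=0)
    null = np.abs(
        _welch_t(flat[idx[:, :n1], :], flat[idx[:, n1:], :], axis=1)
    )  # n_perm x cells
    null = np.where(np.isfinite(null), null, np.inf)
    t_cmp = np.where(np.isfinite(t_obs), np.abs(t_obs), np.inf)
    p = (1.0 + np.count_nonzero(null >= t_cmp[None, :], axis=0)) / (1.0 + cfg.n_perm)

    reject, threshold = bh_fdr(p, q)
    rows = []
    # cells are flattened pair-major then band (C order of (pairs, bands))
    for pi, (ra, rb) in enumerate(pairs):
        for bi, band in enumerate(bands):
            cell = pi * len(bands) + bi
            rows.append(
                {
                    "roi_a": ra,
                    "roi_b": rb,
                    "band": band,
                    "t": t_obs[cell],
                    "p": p[cell],
                    "p_unc_lt_01": p[cell] < 0.01,
                    "fdr_reject": bool(reject[cell]),
                }
            )
    table = pd.DataFrame(rows)
    return StatMap(
        table,
        m=len(pairs) * len(bands),
        q=q,
        fdr_threshold=threshold,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
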