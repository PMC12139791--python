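"""Paired condition inference.

Everything here reduces to one-sample t-tests on within-subject difference
scores (condition A − condition B) and Pearson correlations across subjects.
Cohen's d for the paired design is mean(diff)/sd(diff). The canonical-grid
contrast Bonferroni-corrects over all 64 grid cells — including the symmetric
duplicates — at α = 0.05/64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from connshift.io import ValidationError

logger = logging.getLogger(__name__)

GRID_ALPHA = 0.05
GRID_CELLS = 64  # 8×8 including symmetric duplicates


@dataclass(frozen=True)
class StatResult:
    """One-sample/paired t-test summary on difference scores."""

    estimate: float   # mean difference, input units
    t: float
    df: int
    p: float          # two-tailed
    cohens_d: float   # mean(diff)/sd(diff)
    n: int


def _one_sample_t(diffs: np.ndarray) -> StatResult:
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValidationError("need at least 2 paired observations")
    if np.isnan(diffs).any():
        raise ValidationError("difference scores contain NaN")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            # identical conditions: no evidence of any difference
            return StatResult(estimate=0.0, t=0.0, df=n - 1, p=1.0, cohens_d=0.0, n=n)
        raise ValidationError("zero variance of nonzero differences")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return StatResult(estimate=mean, t=float(t), df=n - 1, p=p, cohens_d=mean / sd, n=n)


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired t-test of condition A vs condition B (one-sample t on A − B)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    return _one_sample_t(x - y)


def change_scores(values_a: Mapping[str, float], values_b: Mapping[str, float]) -> dict[str, float]:
    """Per-subject Δ = A − B over subjects present in both conditions."""
    common = sorted(set(values_a) & set(values_b))
    dropped = (set(values_a) | set(values_b)) - set(common)
    if dropped:
        logger.info("change_scores: dropped unpaired subjects %s", sorted(dropped))
    return {s: values_a[s] - values_b[s] for s in common}


@dataclass(frozen=True)
class GridContrast:
    """Cellwise paired contrast of two per-subject grid stacks."""

    t: np.ndarray            # K×K t-statistics
    p: np.ndarray            # K×K raw two-tailed p
    significant: np.ndarray  # K×K flags, raw p < alpha/n_cells
    n: np.ndarray            # K×K subjects used per cell
    alpha: float
    n_cells: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_cells


def grid_contrast(grids_a: np.ndarray, grids_b: np.ndarray,
                  alpha: float = GRID_ALPHA, n_cells: int | None = None) -> GridContrast:
    """Cellwise paired t over subject-matched K×K grids, Bonferroni-flagged.

    ``grids_a``/``grids_b`` are (n_subjects, K, K) stacks in matched subject
    order. A subject with a NaN cell in either condition is dropped from that
    cell only (logged). Flags mark raw p < alpha / n_cells, where n_cells
    defaults to the full K² family including symmetric duplicates.
    """
    a = np.asarray(grids_a, dtype=float)
    b = np.asarray(grids_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise ValidationError("grid stacks must be matched (n_subjects, K, K)")
    k = a.shape[1]
    if n_cells is None:
        n_cells = k * k
    thresh = alpha / n_cells
    t = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i, k):
            d = a[:, i, j] - b[:, i, j]
            ok = ~np.isnan(d)
            if ok.sum() < d.size:
                logger.info("grid cell (%d,%d): dropped %d subject(s) with undefined cell",
                            i, j, int(d.size - ok.sum()))
            if ok.sum() < 2:
                continue
            res = _one_sample_t(d[ok])
            t[i, j] = t[j, i] = res.t
            p[i, j] = p[j, i] = res.p
            n_used[i, j] = n_used[j, i] = res.n
            sig[i, j] = sig[j, i] = res.p < thresh
    return GridContrast(t=t, p=p, significant=sig, n=n_used, alpha=alpha, n_cells=n_cells)


def _pearson(x: Mapping[str, float] | Sequence[float],
             y: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    if isinstance(x, Mapping) and isinstance(y, Mapping):
        common = sorted(set(x) & set(y))
        xv = np.array([x[s] for s in common], dtype=float)
        yv = np.array([y[s] for s in common], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValidationError("correlation inputs must be matched")
    if xv.size < 3:
        raise ValidationError("need at least 3 common subjects for a correlation")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def consistency_corr(delta_a: Mapping[str, float] | Sequence[float],
                     delta_b: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    """Pearson correlation of condition-change scores between two run types.

    Measures whether the drug moves a network consistently across scan
    contexts (e.g., rest vs task). Two-tailed p.
    """
    return _pearson(delta_a, delta_b)


def brain_behavior_corr(delta_net: Mapping[str, float] | Sequence[float],
                        delta_dprime: Mapping[str, float] | Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between network-strength change and d' change."""
    return _pearson(delta_net, delta_dprime)
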