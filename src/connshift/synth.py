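"""Synthetic paired-condition cohorts with planted network effects.

The generator emulates the statistical structure the analysis assumes, not
BOLD physiology: per subject and run, node time series are drawn from a
multivariate normal whose correlation matrix is a shared factor-structured
baseline; in the drug (MA) condition the correlations on the high-attention
and positive-arousal mask edges are raised, and on the low-attention and
negative-arousal edges lowered, by ``effect_size`` times a subject- and
run-type-specific multiplier. The perturbed matrix is repaired to the
nearest positive-definite correlation matrix before sampling, so the planted
effect lands exactly on the edges the pipeline scores.

Effect heterogeneity is ``g_s + h_{s,t}`` with g_s ~ N(1, subject_sd²)
shared across run types (driving cross-run consistency of drug-induced
change) and h_{s,t} ~ N(0, run_effect_sd²) per run type. The defaults
(subject_sd = run_effect_sd = 0.7) put the within-subject standardized
effect (Cohen's d) of the planted high-attention shift near 1 and the
cross-run consistency correlation near 0.5.

Go/no-go task behavior comes from an equal-variance signal-detection model:
go-trial evidence ~ N(+d/2, 1), no-go evidence ~ N(−d/2, 1), respond iff
evidence exceeds the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from connshift.io import (
    EdgeMask,
    SessionRecord,
    ValidationError,
    write_edge_mask,
    write_manifest,
    write_trials,
)
from connshift.overlap import total_edges
from connshift.strength import CanonicalAssignment

CANONICAL_NETWORKS = (
    "medial_frontal", "frontoparietal", "default_mode", "subcortical_cerebellar",
    "motor", "visual_i", "visual_ii", "visual_association",
)

#: Published edge counts on the 268-node atlas; smaller parcellations get
#: proportionally scaled stand-in masks.
REFERENCE_MASK_SIZES = {
    "high_attention": 757,
    "low_attention": 630,
    "arousal_pos": 469,
    "arousal_neg": 555,
    "valence_pos": 500,   # not printed anywhere; stand-in size
    "valence_neg": 500,
}
_REFERENCE_TOTAL = 35778  # total_edges(268)


@dataclass(frozen=True)
class SynthConfig:
    """Stated world for a paired-condition cohort.

    n_timepoints defaults to 210 (a 7-minute run at TR 2 s). effect_size is
    the correlation-scale shift planted on mask edges in the MA condition.
    """

    n_subjects: int
    n_nodes: int = 268
    n_timepoints: int = 210
    effect_size: float = 0.15
    noise_sd: float = 1.0
    subject_sd: float = 0.7
    run_effect_sd: float = 0.7
    run_types: tuple[str, ...] = ("rest",)
    qc_fail_frac: float = 0.0
    plant_arousal: bool = True
    mask_sizes: Mapping[str, int] | None = None
    include_behavior: bool = False
    behav_base_dprime: float = 2.0
    behav_session_sd: float = 0.4
    behav_practice_shift: float = 0.15  # placebo vs orientation (practice effect)
    behav_ma_shift: float = 0.25        # MA vs placebo mean d' improvement
    behav_coupling: float = 0.0         # links d' change to the network effect
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 20:
            raise ValidationError("n_timepoints must be >= 20 for estimable correlations")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not 0.0 <= self.qc_fail_frac < 1.0:
            raise ValidationError("qc_fail_frac must be in [0, 1)")
        bad = set(self.run_types) - {"rest", "mid", "doors"}
        if bad:
            raise ValidationError(f"unknown run types {sorted(bad)}")

    def resolved_mask_sizes(self) -> dict[str, int]:
        if self.mask_sizes is not None:
            return dict(self.mask_sizes)
        f = total_edges(self.n_nodes) / _REFERENCE_TOTAL
        return {k: max(1, round(v * f)) for k, v in REFERENCE_MASK_SIZES.items()}


@dataclass(frozen=True)
class GradCptGenConfig:
    """Signal-detection world for one go/no-go task run."""

    n_trials: int = 750
    p_nogo: float = 0.10
    d_true: float = 2.0
    criterion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValidationError("n_trials must be positive")
        if not 0.0 < self.p_nogo < 1.0:
            raise ValidationError("p_nogo must lie in (0, 1)")


def gen_gradcpt(config: GradCptGenConfig) -> pd.DataFrame:
    """One simulated task run as a trial table (trial_index, category, responded)."""
    rng = np.random.default_rng(config.seed)
    nogo = rng.random(config.n_trials) < config.p_nogo
    signal = np.where(nogo, -config.d_true / 2.0, config.d_true / 2.0)
    evidence = signal + rng.standard_normal(config.n_trials)
    return pd.DataFrame({
        "trial_index": np.arange(config.n_trials),
        "category": np.where(nogo, "nogo", "go"),
        "responded": evidence > config.criterion,
    })


def gen_masks(n_nodes: int, sizes: Mapping[str, int], seed: int,
              overlaps: Mapping[tuple[str, str], int] | None = None) -> dict[str, EdgeMask]:
    """Sample named edge masks, disjoint by construction unless overlaps ask
    for shared edges.

    ``overlaps[(a, b)] = k`` plants k of mask b's edges inside mask a (a must
    come before b in ``sizes`` order). Raises if the requested edges exceed
    the available node pairs.
    """
    overlaps = dict(overlaps or {})
    m_total = total_edges(n_nodes)
    shared = sum(overlaps.values())
    if sum(sizes.values()) - shared > m_total:
        raise ValidationError(
            f"requested {sum(sizes.values())} edges exceed {m_total} available pairs")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    free = np.ones(m_total, dtype=bool)  # edges not yet used by any mask
    chosen: dict[str, np.ndarray] = {}
    for label, size in sizes.items():
        take = np.zeros(0, dtype=int)
        for (a, b), k in overlaps.items():
            if b == label:
                if a not in chosen:
                    raise ValidationError(f"overlap source {a!r} must precede {b!r}")
                if k > min(len(chosen[a]), size):
                    raise ValidationError(f"overlap {k} infeasible for ({a}, {b})")
                take = np.concatenate([take, rng.choice(chosen[a], size=k, replace=False)])
        take = np.unique(take)
        remaining = size - take.size
        pool = np.where(free)[0]
        if remaining > pool.size:
            raise ValidationError(
                f"mask {label!r}: {remaining} fresh edges requested, {pool.size} free")
        fresh = rng.choice(pool, size=remaining, replace=False) if remaining else np.zeros(0, dtype=int)
        free[fresh] = False
        chosen[label] = np.sort(np.concatenate([take, fresh]).astype(int))
    return {label: EdgeMask(_sym(n_nodes, iu, idx), label=label)
            for label, idx in chosen.items()}


def _sym(n_nodes: int, iu, idx: np.ndarray) -> np.ndarray:
    m = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    m[iu[0][idx], iu[1][idx]] = 1
    return m + m.T


def canonical_assignment(n_nodes: int,
                         networks: Sequence[str] = CANONICAL_NETWORKS) -> CanonicalAssignment:
    """Deterministic stand-in node→network map: near-equal contiguous blocks."""
    k = len(networks)
    labels = tuple(networks[int(i * k / n_nodes)] for i in range(n_nodes))
    return CanonicalAssignment(labels=labels, networks=tuple(networks))


def nearest_pd_correlation(C: np.ndarray, eps: float = 1e-6, max_iter: int = 8) -> np.ndarray:
    """Repair a symmetric matrix to the nearest unit-diagonal PD correlation
    matrix by alternating eigenvalue clipping and diagonal rescaling."""
    A = (C + C.T) / 2.0
    for _ in range(max_iter):
        w, V = np.linalg.eigh(A)
        if w.min() >= eps:
            break
        A = (V * np.clip(w, eps, None)) @ V.T
        d = np.sqrt(np.diagonal(A))
        A = A / np.outer(d, d)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
    if np.linalg.eigvalsh(A).min() <= 0:
        raise ValidationError("covariance not positive definite after repair")
    return A


def _base_correlation(n_nodes: int, rng: np.random.Generator, n_factors: int = 3) -> np.ndarray:
    # low-rank factor structure + unit uniquenesses -> realistic mild positive
    # dependence (typical resting-state Fisher-z means ~0.1-0.3)
    B = rng.normal(0.0, 0.35, size=(n_nodes, n_factors))
    S = B @ B.T + np.eye(n_nodes)
    d = np.sqrt(np.diagonal(S))
    return S / np.outer(d, d)


@dataclass
class GeneratedDataset:
    """In-memory synthetic cohort plus the ground truth that generated it."""

    config: SynthConfig
    masks: dict[str, EdgeMask]
    assignment: CanonicalAssignment
    base_correlation: np.ndarray
    timeseries: dict[tuple[str, str, str], np.ndarray]   # (subject, condition, run_type)
    records: list[SessionRecord]
    subject_effects: dict[str, float]                    # g_s
    run_effects: dict[tuple[str, str], float]            # (subject, run family) -> g_s + h
    trials: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    dprime_true: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.subject_effects)

    @property
    def manifest(self) -> list[SessionRecord]:
        return self.records


def _run_files(run_types: Sequence[str]) -> list[tuple[str, str]]:
    # (run family used for the planted effect, concrete run label)
    out = []
    for rt in run_types:
        if rt == "doors":
            out += [("doors", "doors1"), ("doors", "doors2")]
        else:
            out.append((rt, rt))
    return out


def gen_condition_dataset(config: SynthConfig) -> GeneratedDataset:
    """Generate a full paired-condition cohort under ``config``.

    Per subject × condition × run: node×time series sampled from the planted
    covariance; a session manifest with QC fields (a ``qc_fail_frac``
    Bernoulli fraction of runs planted to fail QC); per-subject randomized
    drug order; optional per-session task behavior.
    """
    root = np.random.SeedSequence(config.seed)
    s_masks, s_base, s_subj, s_runs, s_qc, s_order, s_behav = root.spawn(7)

    masks = gen_masks(config.n_nodes, config.resolved_mask_sizes(),
                      seed=s_masks.generate_state(1)[0] % (2**31))
    assignment = canonical_assignment(config.n_nodes)
    base = _base_correlation(config.n_nodes, np.random.default_rng(s_base))

    # signed planted-edge pattern: +1 on high/arousal_pos, -1 on low/arousal_neg
    plus = masks["high_attention"].matrix.astype(bool)
    minus = masks["low_attention"].matrix.astype(bool)
    if config.plant_arousal:
        plus = plus | masks["arousal_pos"].matrix.astype(bool)
        minus = minus | masks["arousal_neg"].matrix.astype(bool)
    sign = plus.astype(float) - minus.astype(float)

    rng_subj = np.random.default_rng(s_subj)
    rng_run = np.random.default_rng(s_runs)
    rng_qc = np.random.default_rng(s_qc)
    rng_order = np.random.default_rng(s_order)
    rng_behav = np.random.default_rng(s_behav)

    subjects = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    g = {s: rng_subj.normal(1.0, config.subject_sd) for s in subjects}
    run_families = sorted({fam for fam, _ in _run_files(config.run_types)})
    m_eff = {(s, fam): g[s] + rng_run.normal(0.0, config.run_effect_sd)
             for s in subjects for fam in run_families}

    base_chol = np.linalg.cholesky(base) * config.noise_sd

    timeseries: dict[tuple[str, str, str], np.ndarray] = {}
    records: list[SessionRecord] = []
    for s in subjects:
        ma_first = bool(rng_order.random() < 0.5)
        order = {"MA": 1 if ma_first else 2, "PL": 2 if ma_first else 1}
        chol_cache: dict[str, np.ndarray] = {}
        for fam, run in _run_files(config.run_types):
            for cond in ("MA", "PL"):
                if cond == "MA" and config.effect_size > 0:
                    if fam not in chol_cache:
                        target = base + config.effect_size * m_eff[(s, fam)] * sign
                        off = ~np.eye(config.n_nodes, dtype=bool)
                        target[off] = np.clip(target[off], -0.95, 0.95)
                        C = nearest_pd_correlation(target)
                        chol_cache[fam] = np.linalg.cholesky(C) * config.noise_sd
                    L = chol_cache[fam]
                else:
                    L = base_chol
                ts = L @ rng_run.standard_normal((config.n_nodes, config.n_timepoints))
                timeseries[(s, cond, run)] = ts
                fails = rng_qc.random() < config.qc_fail_frac
                if fails:
                    rule = rng_qc.integers(3)
                    qc = dict(
                        max_displacement=rng_qc.uniform(3.05, 6.0) if rule == 0 else rng_qc.uniform(0.3, 2.0),
                        mean_censored_motion=rng_qc.uniform(0.16, 0.3) if rule == 1 else rng_qc.uniform(0.02, 0.12),
                        frac_censored=rng_qc.uniform(0.51, 0.9) if rule == 2 else rng_qc.uniform(0.0, 0.3),
                    )
                else:
                    qc = dict(
                        max_displacement=rng_qc.uniform(0.3, 2.0),
                        mean_censored_motion=rng_qc.uniform(0.02, 0.12),
                        frac_censored=rng_qc.uniform(0.0, 0.3),
                    )
                records.append(SessionRecord(
                    subject_id=s, condition=cond, run_type=run,
                    path=f"ts/{s}_{cond}_{run}.tsv",
                    session_index=order[cond], **qc))

    trials: dict[tuple[str, str], pd.DataFrame] = {}
    d_true: dict[tuple[str, str], float] = {}
    if config.include_behavior:
        for s in subjects:
            d0 = rng_behav.normal(config.behav_base_dprime, 0.5)
            coupling = config.behav_coupling * (g[s] - 1.0)
            d_true[(s, "orientation")] = d0 + rng_behav.normal(0, config.behav_session_sd)
            d_true[(s, "PL")] = (d0 + config.behav_practice_shift
                                 + rng_behav.normal(0, config.behav_session_sd))
            d_true[(s, "MA")] = (d0 + config.behav_practice_shift + config.behav_ma_shift
                                 + coupling + rng_behav.normal(0, config.behav_session_sd))
            for sess in ("orientation", "PL", "MA"):
                cfg = GradCptGenConfig(
                    d_true=max(d_true[(s, sess)], 0.0),
                    seed=int(rng_behav.integers(2**31)))
                trials[(s, sess)] = gen_gradcpt(cfg)

    return GeneratedDataset(config=config, masks=masks, assignment=assignment,
                            base_correlation=base, timeseries=timeseries,
                            records=records, subject_effects=g, run_effects=m_eff,
                            trials=trials, dprime_true=d_true)


def write_dataset(ds: GeneratedDataset, outdir: str | Path) -> Path:
    """Materialize a generated cohort in the on-disk dialects of the readers."""
    out = Path(outdir)
    (out / "ts").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for label, mask in ds.masks.items():
        write_edge_mask(mask, out / "masks" / f"{label}.tsv")
    for (s, cond, run), ts in ds.timeseries.items():
        np.savetxt(out / "ts" / f"{s}_{cond}_{run}.tsv", ts, fmt="%.8g", delimiter="\t")
    write_manifest(ds.records, out / "manifest.csv")
    pd.DataFrame({"node": np.arange(ds.config.n_nodes) + 1,
                  "network": ds.assignment.labels}).to_csv(
        out / "canonical_assignment.csv", index=False)
    if ds.trials:
        (out / "trials").mkdir(exist_ok=True)
        for (s, sess), table in ds.trials.items():
            write_trials(table, out / "trials" / f"{s}_{sess}.csv")
    return out
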