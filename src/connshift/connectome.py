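"""Fisher-z connectomes, run-level QC exclusion, and run combination.

Quality-control thresholds follow the convention that a run is excluded only
when it is strictly beyond the stated bound: maximum censored displacement
> 3 mm, average censored motion > 0.15 mm, or more than 50% of TRs censored.
A run exactly at a bound is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from connshift.io import ConnMatrix, SessionRecord, ValidationError

logger = logging.getLogger(__name__)

MAX_DISPLACEMENT_MM = 3.0
MAX_MEAN_MOTION_MM = 0.15
MAX_FRAC_CENSORED = 0.5

#: r is clipped to ±(1 − R_CLIP_EPS) before atanh so degenerate |r|=1 pairs
#: stay finite and averageable downstream.
R_CLIP_EPS = 1e-7


def compute_fc(ts: np.ndarray, valid_nodes: np.ndarray | None = None) -> ConnMatrix:
    """Fisher z-transformed Pearson correlation connectome from node time series.

    Parameters
    ----------
    ts : array, shape (n_nodes, n_timepoints)
        One run's parcellated time series, one row per atlas node.
    valid_nodes : boolean array, optional
        Nodes with usable data; invalid nodes yield all-NaN rows/columns.

    Returns
    -------
    ConnMatrix with off-diagonal entries atanh(r), r clipped to ±(1 − 1e−7),
    zero diagonal, symmetric on valid nodes.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValidationError("time series must be a 2-D node×time matrix")
    n_nodes, n_t = ts.shape
    if n_t < 3:
        raise ValidationError(f"need at least 3 timepoints, got {n_t}")
    if valid_nodes is None:
        valid = np.ones(n_nodes, dtype=bool)
    else:
        valid = np.asarray(valid_nodes, dtype=bool)
        if valid.shape != (n_nodes,):
            raise ValidationError("valid_nodes length must equal n_nodes")

    sd = ts.std(axis=1)
    dead = np.where(valid & (sd == 0))[0]
    if dead.size:
        raise ValidationError(f"zero-variance time series at valid node(s) {dead.tolist()}")

    z = np.full((n_nodes, n_nodes), np.nan)
    if valid.sum() >= 2:
        r = np.corrcoef(ts[valid])
        r = np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS)
        sub = np.arctanh(r)
        np.fill_diagonal(sub, 0.0)
        idx = np.where(valid)[0]
        z[np.ix_(idx, idx)] = sub
    elif valid.sum() == 1:
        z[np.where(valid)[0][0], np.where(valid)[0][0]] = 0.0
    # keep the convention that valid diagonal entries are 0, invalid NaN
    for i in np.where(valid)[0]:
        z[i, i] = 0.0
    return ConnMatrix(z, valid)


@dataclass(frozen=True)
class QcDecision:
    """Inclusion decision for one run; ``included`` iff ``reasons`` is empty."""

    record: SessionRecord
    included: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.included != (len(self.reasons) == 0):
            raise ValidationError("included must be true iff reasons is empty")


def qc_decision(record: SessionRecord, strict_nodes: bool = True) -> QcDecision:
    """Apply run-level exclusion rules to one session record."""
    reasons: list[str] = []
    qc = (record.max_displacement, record.mean_censored_motion, record.frac_censored)
    if any(not np.isfinite(v) for v in qc) or record.path == "":
        reasons.append("missing_data")
    else:
        if record.max_displacement > MAX_DISPLACEMENT_MM:
            reasons.append("max_disp")
        if record.mean_censored_motion > MAX_MEAN_MOTION_MM:
            reasons.append("mean_motion")
        if record.frac_censored > MAX_FRAC_CENSORED:
            reasons.append("censor_frac")
    if strict_nodes and record.missing_nodes:
        reasons.append("missing_nodes")
    return QcDecision(record, included=not reasons, reasons=tuple(reasons))


def qc_filter(records: Sequence[SessionRecord], strict_nodes: bool = True) -> list[QcDecision]:
    """Run-level QC over a manifest; order-independent, one decision per record.

    With ``strict_nodes`` (default) a run listing missing nodes is excluded,
    reading the "insufficient brain coverage" rule as a run exclusion; with
    ``strict_nodes=False`` missing nodes only NaN-out their edges downstream.
    """
    decisions = [qc_decision(r, strict_nodes=strict_nodes) for r in records]
    for d in decisions:
        if not d.included:
            logger.info("excluded %s/%s/%s: %s", d.record.subject_id,
                        d.record.condition, d.record.run_type, ",".join(d.reasons))
    return decisions


def combine_doors(run1: ConnMatrix | None, run2: ConnMatrix | None) -> ConnMatrix | None:
    """Combine the two reward-task runs: elementwise mean if both usable,
    pass-through if one, absent if neither."""
    if run1 is None and run2 is None:
        return None
    if run1 is None:
        return run2
    if run2 is None:
        return run1
    if run1.values.shape != run2.values.shape:
        raise ValidationError(
            f"shape mismatch {run1.values.shape} vs {run2.values.shape}")
    values = (run1.values + run2.values) / 2.0
    valid = run1.valid_nodes & run2.valid_nodes
    return ConnMatrix(values, valid, meta=run1.meta)


def pair_conditions(decisions: Sequence[QcDecision], run_type: str) -> list[str]:
    """Subjects with an included run of ``run_type`` in both MA and PL.

    ``run_type="doors"`` counts a subject usable in a condition if either
    doors run survived QC (the two runs are averaged downstream).
    """
    run_types = ("doors1", "doors2") if run_type == "doors" else (run_type,)
    have: dict[str, set[str]] = {}
    for d in decisions:
        if d.included and d.record.run_type in run_types:
            have.setdefault(d.record.subject_id, set()).add(d.record.condition)
    return sorted(s for s, conds in have.items() if {"MA", "PL"} <= conds)
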