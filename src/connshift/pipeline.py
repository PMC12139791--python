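"""Glue between the synthetic generator / on-disk manifests and the analyses.

These helpers run the standard chain — QC filter, Fisher-z connectome per
run, doors-run averaging, MA/PL pairing — and tabulate network strengths and
canonical grids, so analysis drivers, the CLI, and calibration tests all
share one code path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from connshift.connectome import combine_doors, compute_fc, pair_conditions, qc_filter
from connshift.io import ConnMatrix, EdgeMask, SessionRecord, ValidationError, read_manifest
from connshift.strength import CanonicalAssignment, canonical_grid, network_strength_with_count
from connshift.synth import GeneratedDataset


def _valid_from_record(record: SessionRecord, n_nodes: int) -> np.ndarray:
    valid = np.ones(n_nodes, dtype=bool)
    for i in record.missing_nodes:
        valid[i] = False
    return valid


def paired_connectomes(records: Sequence[SessionRecord],
                       loader: Callable[[SessionRecord], np.ndarray],
                       run_type: str,
                       strict_nodes: bool = True) -> dict[tuple[str, str], ConnMatrix]:
    """QC-filter, compute Fisher-z connectomes, combine doors runs, and keep
    only subjects usable in both conditions.

    Returns ``{(subject, condition): ConnMatrix}`` where the matrix carries
    its SessionRecord as meta. ``run_type="doors"`` averages the two runs
    when both survive QC and passes the single survivor through otherwise.
    """
    decisions = qc_filter(records, strict_nodes=strict_nodes)
    included = {(d.record.subject_id, d.record.condition, d.record.run_type): d.record
                for d in decisions if d.included}
    subjects = pair_conditions(decisions, run_type)
    out: dict[tuple[str, str], ConnMatrix] = {}
    run_labels = ("doors1", "doors2") if run_type == "doors" else (run_type,)
    for subj in subjects:
        for cond in ("MA", "PL"):
            conns = []
            for run in run_labels:
                rec = included.get((subj, cond, run))
                if rec is None:
                    conns.append(None)
                    continue
                ts = loader(rec)
                conn = compute_fc(ts, _valid_from_record(rec, ts.shape[0]))
                conns.append(conn.with_meta(rec))
            combined = conns[0] if len(conns) == 1 else combine_doors(conns[0], conns[1])
            if combined is None:  # cannot happen for paired subjects, by construction
                raise ValidationError(f"no usable {run_type} run for paired subject {subj}")
            meta = next(c.meta for c in conns if c is not None)
            out[(subj, cond)] = combined.with_meta(meta)
    return out


def dataset_connectomes(ds: GeneratedDataset, run_type: str,
                        strict_nodes: bool = True) -> dict[tuple[str, str], ConnMatrix]:
    """Paired connectomes straight from an in-memory synthetic cohort."""
    key = {(r.subject_id, r.condition, r.run_type): r for r in ds.records}

    def loader(rec: SessionRecord) -> np.ndarray:
        return ds.timeseries[(rec.subject_id, rec.condition, rec.run_type)]

    return paired_connectomes(ds.records, loader, run_type, strict_nodes=strict_nodes)


def manifest_connectomes(manifest_path: str | Path, run_type: str,
                         strict_nodes: bool = True) -> dict[tuple[str, str], ConnMatrix]:
    """Paired connectomes from a manifest whose paths are relative to it."""
    manifest_path = Path(manifest_path)
    records = read_manifest(manifest_path)
    base = manifest_path.parent

    def loader(rec: SessionRecord) -> np.ndarray:
        return np.loadtxt(base / rec.path, delimiter="\t", ndmin=2)

    return paired_connectomes(records, loader, run_type, strict_nodes=strict_nodes)


def strength_table(conns: Mapping[tuple[str, str], ConnMatrix],
                   masks: Mapping[str, EdgeMask]) -> pd.DataFrame:
    """Network strength per scan for every mask, plus high−low difference
    scores for any high/low mask pair sharing a prefix (attention, arousal,
    valence)."""
    rows = []
    for (subj, cond), conn in sorted(conns.items()):
        row: dict = {"subject": subj, "condition": cond}
        for label, mask in masks.items():
            value, n_used = network_strength_with_count(conn, mask)
            row[label] = value
            row[f"{label}_edges_used"] = n_used
        for prefix, hi, lo in (("attention", "high_attention", "low_attention"),
                               ("arousal", "arousal_pos", "arousal_neg"),
                               ("valence", "valence_pos", "valence_neg")):
            if hi in masks and lo in masks:
                row[f"{prefix}_diff"] = row[hi] - row[lo]
        rows.append(row)
    return pd.DataFrame(rows)


def paired_values(table: pd.DataFrame, column: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Subject-aligned (MA, PL) value vectors from a strength table."""
    ma = table[table.condition == "MA"].set_index("subject")[column]
    pl = table[table.condition == "PL"].set_index("subject")[column]
    subjects = sorted(set(ma.index) & set(pl.index))
    return subjects, ma.loc[subjects].to_numpy(), pl.loc[subjects].to_numpy()


def grid_stacks(conns: Mapping[tuple[str, str], ConnMatrix],
                assignment: CanonicalAssignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Subject-matched stacks of canonical K×K grids for MA and PL."""
    subjects = sorted({s for (s, _) in conns})
    ma = np.stack([canonical_grid(conns[(s, "MA")], assignment) for s in subjects])
    pl = np.stack([canonical_grid(conns[(s, "PL")], assignment) for s in subjects])
    return subjects, ma, pl
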