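"""Go/no-go sustained-attention task scoring and subject grouping.

The task is a gradual-onset continuous performance task (gradCPT): press on
frequent go trials (city scenes, 90%), withhold on rare no-go trials
(mountain scenes, 10%). Performance is signal-detection sensitivity
d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate), with the standard 1/(2N)
correction applied only to rates of exactly 0 or 1 so both z-scores stay
finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from connshift.io import SessionRecord, ValidationError


@dataclass(frozen=True)
class GradCptRun:
    """Outcome counts and sensitivity for one task run."""

    n_go: int
    n_nogo: int
    hits: int
    false_alarms: int
    hit_rate: float       # after extreme-rate correction
    fa_rate: float
    dprime: float


def _corrected_rate(count: int, n: int) -> float:
    # 1/(2N) rule: 0 -> 1/(2N), 1 -> 1 - 1/(2N); interior rates untouched
    rate = count / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity from (already corrected) hit and false-alarm rates."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValidationError("rates must lie strictly inside (0, 1); apply correction first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def score_gradcpt(trials: pd.DataFrame) -> GradCptRun:
    """Score a trial table (columns category∈{go,nogo}, responded) into d'.

    A hit is a response on a go trial; a false alarm a response on a no-go
    trial. Raises if either trial category is absent.
    """
    cat = trials["category"].to_numpy()
    resp = trials["responded"].to_numpy(dtype=bool)
    go = cat == "go"
    nogo = cat == "nogo"
    n_go, n_nogo = int(go.sum()), int(nogo.sum())
    if n_go == 0 or n_nogo == 0:
        raise ValidationError(
            f"need at least one trial of each category (go={n_go}, nogo={n_nogo})")
    hits = int(resp[go].sum())
    fas = int(resp[nogo].sum())
    hit_rate = _corrected_rate(hits, n_go)
    fa_rate = _corrected_rate(fas, n_nogo)
    return GradCptRun(n_go=n_go, n_nogo=n_nogo, hits=hits, false_alarms=fas,
                      hit_rate=hit_rate, fa_rate=fa_rate,
                      dprime=dprime_from_rates(hit_rate, fa_rate))


def median_split(scores: Mapping[str, float]) -> dict[str, set[str]]:
    """Split subjects at the median score: strictly above → high, else low.

    Subjects exactly at the median go to the low group (deterministic tie
    rule). Raises if fewer than 2 subjects or all scores are identical.
    """
    if len(scores) < 2:
        raise ValidationError("median split needs at least 2 subjects")
    vals = np.array(list(scores.values()), dtype=float)
    if np.ptp(vals) == 0:
        raise ValidationError("all scores identical; no split possible")
    med = float(np.median(vals))
    high = {s for s, v in scores.items() if v > med}
    low = set(scores) - high
    return {"high": high, "low": low}


def order_split(records: Sequence[SessionRecord]) -> dict[str, set[str]]:
    """Partition subjects by which condition came first (drug-order analysis).

    Requires ``session_index`` on every record; each subject's first-session
    condition decides membership in ``MA_first`` or ``PL_first``.
    """
    first: dict[str, tuple[int, str]] = {}
    for r in records:
        if r.session_index is None:
            raise ValidationError(
                f"record {r.subject_id}/{r.condition}/{r.run_type} lacks session_index")
        cur = first.get(r.subject_id)
        if cur is None or r.session_index < cur[0]:
            first[r.subject_id] = (r.session_index, r.condition)
    out = {"MA_first": set(), "PL_first": set()}
    for subject, (_, cond) in first.items():
        out["MA_first" if cond == "MA" else "PL_first"].add(subject)
    return out
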