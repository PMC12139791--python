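"""Cross-run consistency of drug-induced network change, and brain-behavior
coupling.

Correlates each subject's MA-minus-PL change in attention/arousal/valence
difference scores between run-type pairs (rest-doors, rest-MID, doors-MID),
and correlates attention-network change with d' change. In the generated
world the subject-level effect is shared across run types (consistency
r ~ 0.5) while behavior change is uncoupled by default (brain-behavior
r ~ 0). Writes results/consistency.csv and results/brain_behavior.csv.
"""

import sys
from itertools import combinations
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEFAULT_SEED, ensure_results, make_cohort

import connshift as cs
from connshift import pipeline


def main(seed: int = DEFAULT_SEED) -> None:
    results = ensure_results()
    ds = make_cohort(seed)

    deltas: dict[tuple[str, str], dict[str, float]] = {}
    for rt in ("rest", "doors", "mid"):
        conns = pipeline.dataset_connectomes(ds, rt)
        table = pipeline.strength_table(conns, ds.masks)
        for measure in ("attention_diff", "arousal_diff", "valence_diff"):
            subs, ma, pl = pipeline.paired_values(table, measure)
            deltas[(rt, measure)] = dict(zip(subs, ma - pl))

    rows = []
    for rt_a, rt_b in combinations(("rest", "doors", "mid"), 2):
        for measure in ("attention_diff", "arousal_diff", "valence_diff"):
            r, p = cs.consistency_corr(deltas[(rt_a, measure)], deltas[(rt_b, measure)])
            n = len(set(deltas[(rt_a, measure)]) & set(deltas[(rt_b, measure)]))
            rows.append({"run_a": rt_a, "run_b": rt_b, "measure": measure,
                         "r": r, "p": p, "n": n})
    consistency = pd.DataFrame(rows)
    consistency.to_csv(results / "consistency.csv", index=False)

    d_beh = {s: (cs.score_gradcpt(ds.trials[(s, "MA")]).dprime
                 - cs.score_gradcpt(ds.trials[(s, "PL")]).dprime)
             for s in ds.subjects}
    bb_rows = []
    for rt in ("rest", "doors", "mid"):
        r, p = cs.brain_behavior_corr(deltas[(rt, "attention_diff")], d_beh)
        n = len(set(deltas[(rt, "attention_diff")]) & set(d_beh))
        bb_rows.append({"run_type": rt, "measure": "attention_diff_vs_dprime",
                        "r": r, "p": p, "n": n})
    brain_behavior = pd.DataFrame(bb_rows)
    brain_behavior.to_csv(results / "brain_behavior.csv", index=False)

    att = consistency[consistency.measure == "attention_diff"]
    print("cross-run consistency of attention-network change:")
    for row in att.itertuples():
        print(f"  {row.run_a}-{row.run_b}: r = {row.r:.3f}, p = {row.p:.3g} (n={row.n})")
    print("attention change vs d' change (uncoupled world):")
    for row in brain_behavior.itertuples():
        print(f"  {row.run_type}: r = {row.r:+.3f}, p = {row.p:.3g}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
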