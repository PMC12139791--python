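"""Condition contrasts on network strength and the canonical-grid contrast.

For each run type: score every paired connectome against the attention,
arousal and valence masks, run paired MA-vs-PL t-tests on each strength and
difference score (the table-2-shaped report), and for rest compute the 8x8
canonical-network contrast with Bonferroni alpha = 0.05/64 (the heat-map
report). Writes results/strengths_<runtype>.csv,
results/condition_contrasts.csv and results/grid_contrast.csv.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEFAULT_SEED, ensure_results, make_cohort

from connshift import group_stats, pipeline


def main(seed: int = DEFAULT_SEED) -> None:
    results = ensure_results()
    ds = make_cohort(seed)

    contrast_rows = []
    for rt in ("rest", "doors", "mid"):
        conns = pipeline.dataset_connectomes(ds, rt)
        table = pipeline.strength_table(conns, ds.masks)
        table.to_csv(results / f"strengths_{rt}.csv", index=False)
        for measure in ("high_attention", "low_attention", "attention_diff",
                        "arousal_diff", "valence_diff"):
            _, ma, pl = pipeline.paired_values(table, measure)
            res = group_stats.paired_t(ma, pl)
            contrast_rows.append({"run_type": rt, "measure": measure,
                                  **dataclasses.asdict(res)})
    contrasts = pd.DataFrame(contrast_rows)
    contrasts.to_csv(results / "condition_contrasts.csv", index=False)

    conns = pipeline.dataset_connectomes(ds, "rest")
    _, ma_grids, pl_grids = pipeline.grid_stacks(conns, ds.assignment)
    contrast = group_stats.grid_contrast(ma_grids, pl_grids)
    nets = ds.assignment.networks
    rows = [{"net_a": nets[a], "net_b": nets[b], "t": contrast.t[a, b],
             "p": contrast.p[a, b], "significant": bool(contrast.significant[a, b])}
            for a in range(8) for b in range(8)]
    pd.DataFrame(rows).to_csv(results / "grid_contrast.csv", index=False)

    rest = contrasts[contrasts.run_type == "rest"].set_index("measure")
    print("rest condition contrasts (MA - PL):")
    for m in ("high_attention", "low_attention", "attention_diff",
              "arousal_diff", "valence_diff"):
        r = rest.loc[m]
        print(f"  {m:16s} M = {r.estimate:+.4f}, t({int(r.df)}) = {r.t:6.2f}, "
              f"p = {r.p:.2e}, d = {r.cohens_d:+.2f}")
    n_sig = int(contrast.significant.sum())
    print(f"canonical grid: {n_sig}/64 cells significant at 0.05/64")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
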