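"""Task-performance scoring: d' per session, condition contrast, splits.

Scores every generated go/no-go run into d', tests the MA-vs-PL improvement
with a paired t-test, splits subjects at the orientation-session median, and
partitions by drug order. Writes results/behavior_dprime.csv and
results/behavior_tests.csv.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEFAULT_SEED, ensure_results, make_cohort

import connshift as cs


def main(seed: int = DEFAULT_SEED) -> None:
    results = ensure_results()
    ds = make_cohort(seed)

    rows = []
    for (subj, session), trials in sorted(ds.trials.items()):
        run = cs.score_gradcpt(trials)
        rows.append({"subject": subj, "session": session,
                     **dataclasses.asdict(run)})
    dprime = pd.DataFrame(rows)
    dprime.to_csv(results / "behavior_dprime.csv", index=False)

    wide = dprime.pivot(index="subject", columns="session", values="dprime")
    test_rows = []
    for a, b in (("MA", "PL"), ("MA", "orientation"), ("PL", "orientation")):
        res = cs.paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        test_rows.append({"contrast": f"{a}-{b}", "group": "all",
                          **dataclasses.asdict(res)})

    groups = cs.median_split(wide["orientation"].to_dict())
    for name, members in groups.items():
        sub = wide.loc[sorted(members)]
        res = cs.paired_t(sub["MA"].to_numpy(), sub["PL"].to_numpy())
        test_rows.append({"contrast": "MA-PL", "group": f"{name}_performers",
                          **dataclasses.asdict(res)})

    order = cs.order_split(ds.records)
    for name, members in order.items():
        if len(members) >= 2:
            sub = wide.loc[sorted(members)]
            res = cs.paired_t(sub["MA"].to_numpy(), sub["PL"].to_numpy())
            test_rows.append({"contrast": "MA-PL", "group": name,
                              **dataclasses.asdict(res)})
    tests = pd.DataFrame(test_rows)
    tests.to_csv(results / "behavior_tests.csv", index=False)

    main_row = tests[(tests.contrast == "MA-PL") & (tests.group == "all")].iloc[0]
    print(f"d' MA vs PL: M = {main_row.estimate:+.3f}, "
          f"t({int(main_row.df)}) = {main_row.t:.2f}, p = {main_row.p:.3g}")
    print(f"median split: {len(groups['high'])} high / {len(groups['low'])} low; "
          f"order: {len(order['MA_first'])} MA-first / {len(order['PL_first'])} PL-first")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
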