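"""QC filtering and paired Fisher-z connectome counts per run type.

Emulates the study's exclusion bookkeeping: how many runs fail each motion
rule, and how many subjects keep a usable run in both conditions per run
type (the doors pairing accepts either of its two runs and averages when
both survive). Writes results/qc_summary.csv.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEFAULT_SEED, ensure_results, make_cohort

from connshift import pipeline
from connshift.connectome import pair_conditions, qc_filter


def main(seed: int = DEFAULT_SEED) -> None:
    results = ensure_results()
    ds = make_cohort(seed)
    decisions = qc_filter(ds.records)

    reasons = Counter(r for d in decisions for r in d.reasons)
    n_excluded = sum(not d.included for d in decisions)
    rows = [{"item": "runs_total", "value": len(decisions)},
            {"item": "runs_excluded", "value": n_excluded}]
    rows += [{"item": f"reason_{k}", "value": v} for k, v in sorted(reasons.items())]
    for rt in ("rest", "doors", "mid"):
        pairs = pair_conditions(decisions, rt)
        rows.append({"item": f"paired_subjects_{rt}", "value": len(pairs)})
        conns = pipeline.dataset_connectomes(ds, rt)
        rows.append({"item": f"connectomes_{rt}", "value": len(conns)})
    pd.DataFrame(rows).to_csv(results / "qc_summary.csv", index=False)
    print(f"{n_excluded}/{len(decisions)} runs excluded "
          f"({dict(reasons)}); paired subjects per run type: "
          + ", ".join(f"{r['item'].split('_')[-1]}={r['value']}"
                      for r in rows if r["item"].startswith("paired_subjects")))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
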