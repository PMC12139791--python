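"""Condition classification from resting-state edges.

Paired leave-one-subject-out linear SVM on the rest connectomes, pair-flip
permutation null, and top-weight edge selection (percentile rule, q = 2.5,
mirroring the published selection step). Writes
results/classifier_report.json and the selected-edge masks under
scratch/classifier/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEFAULT_SEED, ensure_results, make_cohort

from connshift import pipeline
from connshift.classifier import build_design, loso_paired_cv, permutation_test, select_edges
from connshift.io import write_edge_mask

N_PERM = 199  # desk-scale stand-in for the published 1,000 relabelings


def main(seed: int = DEFAULT_SEED) -> None:
    results = ensure_results()
    ds = make_cohort(seed)
    conns = pipeline.dataset_connectomes(ds, "rest")
    design = build_design([(s, c, conn) for (s, c), conn in sorted(conns.items())])

    report = loso_paired_cv(design)
    perm = permutation_test(design, n_perm=N_PERM, seed=seed)
    selection = select_edges(report.mean_weights, rule="percentile", q=2.5)

    scratch = Path(__file__).resolve().parent.parent / "scratch" / "classifier"
    scratch.mkdir(parents=True, exist_ok=True)
    np.savetxt(scratch / "mean_weights.tsv", report.mean_weights,
               fmt="%.17g", delimiter="\t")
    write_edge_mask(selection.positive_mask, scratch / "svc_positive.tsv")
    write_edge_mask(selection.negative_mask, scratch / "svc_negative.tsv")

    summary = {
        "n_subjects": len(report.per_fold_predictions),
        "n_scans": design.n_scans,
        "n_edges": int(design.X.shape[1]),
        "accuracy": report.accuracy,
        "perm_p": perm.perm_p,
        "n_perm": N_PERM,
        "null_accuracy_mean": float(perm.null_accuracies.mean()),
        "selection_rule": "percentile q=2.5",
        "pos_threshold": selection.pos_threshold,
        "neg_threshold": selection.neg_threshold,
        "n_positive_edges": selection.positive_mask.edge_count,
        "n_negative_edges": selection.negative_mask.edge_count,
        "seed": seed,
    }
    (results / "classifier_report.json").write_text(json.dumps(summary, indent=2))
    print(f"LOSO accuracy {report.accuracy:.4f} over {design.n_scans} held-out scans "
          f"(null mean {summary['null_accuracy_mean']:.3f}, perm p = {perm.perm_p:.4g})")
    print(f"selected {summary['n_positive_edges']} positive / "
          f"{summary['n_negative_edges']} negative edges "
          f"(weight cutoffs {selection.pos_threshold:.4g} / {selection.neg_threshold:.4g})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED)
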