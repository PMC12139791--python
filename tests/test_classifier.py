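"""Design building, paired-LOSO SVM, permutation null, edge selection."""

import warnings

import numpy as np
import pytest

import connshift as cs
from connshift.classifier import (
    build_design,
    loso_accuracy,
    loso_paired_cv,
    permutation_test,
    select_edges,
)
from connshift.io import ValidationError

from conftest import random_conn


def make_conns(rng, n_subjects, n_nodes, effect=0.0, nan_edge=None):
    """Paired scans: MA scans get +effect added on a fixed edge block."""
    out = []
    for i in range(n_subjects):
        for cond in ("MA", "PL"):
            conn = random_conn(rng, n_nodes)
            if cond == "MA" and effect:
                conn.values[:5, :5] += effect
                np.fill_diagonal(conn.values, 0.0)
            if nan_edge is not None and (i, cond) == (0, "MA"):
                a, b = nan_edge
                conn.values[a, b] = conn.values[b, a] = np.nan
            out.append((f"s{i}", cond, conn))
    return out


class TestBuildDesign:
    def test_dimension_arithmetic(self, rng):
        design = build_design(make_conns(rng, 10, 30))
        assert design.X.shape == (20, 435)
        assert len(design.subject_ids) == 10

    def test_single_nan_edge_dropped_globally(self, rng):
        design = build_design(make_conns(rng, 10, 30, nan_edge=(2, 7)))
        assert design.X.shape == (20, 434)
        assert design.n_dropped_edges == 1

    def test_devectorize_round_trip(self, rng):
        conns = make_conns(rng, 3, 12)
        design = build_design(conns)
        original = conns[0][2].values
        back = design.devectorize(design.X[0])
        iu = np.triu_indices(12, k=1)
        assert np.array_equal(back[iu], original[iu])
        assert np.array_equal(back, back.T, equal_nan=True)

    def test_all_nan_rejected(self, rng):
        conn = cs.ConnMatrix(np.full((5, 5), np.nan), np.zeros(5, bool))
        with pytest.raises(ValidationError):
            build_design([("s1", "MA", conn), ("s1", "PL", conn),
                          ("s2", "MA", conn), ("s2", "PL", conn),
                          ("s3", "MA", conn), ("s3", "PL", conn)])


class TestLosoPairedCv:
    def test_separable_effect_perfect_accuracy(self, rng):
        design = build_design(make_conns(rng, 8, 20, effect=3.0))
        report = loso_paired_cv(design)
        assert report.accuracy == 1.0
        assert report.mean_weights.shape == (20, 20)
        w = report.mean_weights
        off = ~np.isnan(w)
        assert np.array_equal(w[off], w.T[off])

    def test_every_subject_gets_a_fold(self, rng):
        design = build_design(make_conns(rng, 6, 15, effect=2.0))
        report = loso_paired_cv(design)
        assert set(report.per_fold_predictions) == {f"s{i}" for i in range(6)}
        assert all(len(v) == 2 for v in report.per_fold_predictions.values())

    def test_single_scan_subject_held_out_alone(self, rng):
        conns = make_conns(rng, 6, 15, effect=2.5)
        conns = [c for c in conns if c[:2] != ("s0", "PL")]  # s0 has MA only
        report = loso_paired_cv(build_design(conns))
        assert len(report.per_fold_predictions["s0"]) == 1
        assert len(report.per_fold_predictions["s1"]) == 2

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            loso_paired_cv(build_design(make_conns(rng, 2, 10)))

    def test_single_class_training_fold_rejected(self, rng):
        conns = [(s, "MA", random_conn(rng, 10)) for s in ("a", "b", "c")]
        conns.append(("a", "PL", random_conn(rng, 10)))
        with pytest.raises(ValidationError, match="single-class"):
            loso_paired_cv(build_design(conns))

    def test_gram_fast_path_matches_feature_path(self, rng):
        """Precomputed-kernel CV (used by the permutation loop) reproduces the
        linear-kernel CV accuracy exactly."""
        design = build_design(make_conns(rng, 8, 20, effect=0.4))
        assert loso_accuracy(design) == loso_paired_cv(design).accuracy


class TestPermutationTest:
    def test_strong_effect_attains_floor(self, rng):
        # 16 subjects: the chance of redrawing the identity flip (the only
        # permutation that ties a separable observed accuracy) is 100/2^16
        design = build_design(make_conns(rng, 16, 20, effect=3.0))
        perm = permutation_test(design, n_perm=100, seed=7)
        assert perm.perm_p == pytest.approx(1 / 101)

    def test_anti_learning_structure_gives_large_p(self, rng):
        """If observed accuracy sits below the null median, p > 0.5.

        Alternating the planted effect's sign across subjects makes every
        LOSO fold's training majority point the wrong way for the held-out
        subject, so observed accuracy falls near 0 while the flip null stays
        centered at 0.5.
        """
        conns = []
        for i in range(8):
            sign = 1.0 if i % 2 == 0 else -1.0
            for cond in ("MA", "PL"):
                conn = random_conn(rng, 20)
                if cond == "MA":
                    conn.values[:5, :5] += 3.0 * sign
                    np.fill_diagonal(conn.values, 0.0)
                conns.append((f"s{i}", cond, conn))
        perm = permutation_test(build_design(conns), n_perm=100, seed=7)
        assert perm.observed_accuracy < np.median(perm.null_accuracies)
        assert perm.perm_p > 0.5

    def test_deterministic_given_seed(self, rng):
        design = build_design(make_conns(rng, 6, 15, effect=0.3))
        a = permutation_test(design, n_perm=30, seed=42)
        b = permutation_test(design, n_perm=30, seed=42)
        assert a.perm_p == b.perm_p
        assert np.array_equal(a.null_accuracies, b.null_accuracies)

    def test_invalid_n_perm_rejected(self, rng):
        design = build_design(make_conns(rng, 4, 10))
        with pytest.raises(ValidationError):
            permutation_test(design, n_perm=0, seed=1)

    def test_full_shuffle_scheme_available(self, rng):
        design = build_design(make_conns(rng, 6, 15, effect=3.0))
        perm = permutation_test(design, n_perm=50, seed=3, scheme="full_shuffle")
        assert perm.perm_p <= 0.1


class TestSelectEdges:
    def test_all_zero_weights_give_empty_masks(self):
        w = np.zeros((10, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_edges(w, rule="absolute", pos_threshold=0.002,
                               neg_threshold=-0.0023)
        assert sel.positive_mask.edge_count == 0
        assert sel.negative_mask.edge_count == 0

    def test_absolute_thresholds_published_counts(self, rng):
        """A synthetic 268-node weight map with exactly 135 edges above 0.0020
        and 168 below −0.0023 selects exactly those counts."""
        n = 268
        iu = np.triu_indices(n, k=1)
        vals = rng.uniform(-0.0015, 0.0015, size=iu[0].size)  # interior mass
        vals[:135] = rng.uniform(0.0021, 0.01, size=135)
        vals[135:135 + 168] = rng.uniform(-0.01, -0.0024, size=168)
        w = np.zeros((n, n))
        w[iu] = vals
        w = w + w.T
        sel = select_edges(w, rule="absolute", pos_threshold=0.0020,
                           neg_threshold=-0.0023)
        assert sel.positive_mask.edge_count == 135
        assert sel.negative_mask.edge_count == 168

    def test_percentile_counting_oracle(self, rng):
        """Top 2.5% of 35,778 finite weights is floor(894.45) = 894 per side."""
        n = 268
        iu = np.triu_indices(n, k=1)
        w = np.zeros((n, n))
        w[iu] = rng.normal(size=iu[0].size)
        w = w + w.T
        sel = select_edges(w, rule="percentile", q=2.5)
        assert sel.positive_mask.edge_count == 894
        assert sel.negative_mask.edge_count == 894

    def test_masks_disjoint_and_thresholds_honored(self, rng):
        n = 30
        iu = np.triu_indices(n, k=1)
        w = np.zeros((n, n))
        w[iu] = rng.normal(scale=0.005, size=iu[0].size)
        w = w + w.T
        sel = select_edges(w, rule="percentile", q=10)
        assert cs.overlap_count(sel.positive_mask, sel.negative_mask) == 0
        ii, jj = sel.positive_mask.edge_indices()
        assert (w[ii, jj] >= sel.pos_threshold).all()

    def test_nan_edges_never_selected(self, rng):
        w = rng.normal(size=(12, 12))
        w = (w + w.T) / 2
        w[0, 1] = w[1, 0] = np.nan
        sel = select_edges(w, rule="percentile", q=20)
        assert sel.positive_mask.matrix[0, 1] == 0
        assert sel.negative_mask.matrix[0, 1] == 0
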