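"""Paired t-tests, the Bonferroni grid contrast, change scores, correlations."""

import numpy as np
import pytest

import connshift as cs
from connshift.group_stats import change_scores, grid_contrast, paired_t
from connshift.io import ValidationError


def _betacf(a, b, x, tol=3e-15, max_iter=300):
    """Continued fraction for the incomplete beta (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    d = 1.0 / (d if abs(d) > tiny else tiny)
    h = d
    for m in range(1, max_iter):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        d = 1.0 / (d if abs(d) > tiny else tiny)
        c = 1.0 + aa / (c if abs(c) > tiny else tiny)
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        d = 1.0 / (d if abs(d) > tiny else tiny)
        c = 1.0 + aa / (c if abs(c) > tiny else tiny)
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < tol:
            break
    return h


def betainc_cf(a, b, x):
    """Regularized incomplete beta I_x(a, b), independent of scipy."""
    import math
    if x in (0.0, 1.0):
        return x
    ln_front = (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
                + a * math.log(x) + b * math.log1p(-x))
    if x < (a + 1.0) / (a + b + 2.0):
        return math.exp(ln_front) * _betacf(a, b, x) / a
    return 1.0 - math.exp(ln_front) * _betacf(b, a, 1.0 - x) / b


def t_two_tailed_p(t, df):
    """Two-tailed t-tail probability via the incomplete-beta identity."""
    return betainc_cf(df / 2.0, 0.5, df / (df + t * t))


class TestPairedT:
    def test_identical_conditions(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.cohens_d == 0.0

    def test_hand_computed_closed_form(self):
        # differences (1..5): mean 3, sd sqrt(2.5); t = 3/(1.5811/sqrt(5))
        res = paired_t([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.t == pytest.approx(4.242640687119285, abs=1e-12)
        assert res.df == 4
        assert res.estimate == pytest.approx(3.0)
        assert res.cohens_d == pytest.approx(3.0 / np.sqrt(2.5), abs=1e-12)

    def test_p_matches_incomplete_beta_oracle(self):
        """p(t=2, df=60) against an independent continued-fraction betainc."""
        x = np.arange(61, dtype=float)
        # build data whose paired t is exactly 2.0 with df=60
        diffs = np.zeros(61)
        diffs[:61] = x - x.mean()
        sd = diffs.std(ddof=1)
        target_mean = 2.0 * sd / np.sqrt(61)
        res = paired_t(diffs + target_mean, np.zeros(61))
        assert res.t == pytest.approx(2.0, abs=1e-12)
        assert res.p == pytest.approx(t_two_tailed_p(2.0, 60), abs=1e-10)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])

    def test_sign_convention(self, rng):
        x = rng.normal(1.0, 0.3, size=20)
        y = rng.normal(0.0, 0.3, size=20)
        res = paired_t(x, y)
        assert np.sign(res.t) == np.sign(res.estimate) == 1.0


class TestGridContrast:
    def test_all_zero_differences_nothing_significant(self, rng):
        grids = rng.normal(size=(10, 8, 8))
        grids = (grids + grids.transpose(0, 2, 1)) / 2
        out = grid_contrast(grids, grids.copy())
        assert not out.significant.any()
        assert (out.t == 0).all() and (out.p == 1).all()

    def test_planted_cell_and_mirror_flagged(self, rng):
        base = rng.normal(size=(20, 8, 8)) * 0.1
        base = (base + base.transpose(0, 2, 1)) / 2
        ma = base.copy()
        ma[:, 2, 5] += 5.0
        ma[:, 5, 2] += 5.0
        ma += rng.normal(0, 0.05, size=(20, 1, 1))  # subject jitter so sd > 0
        out = grid_contrast(ma, base)
        flagged = set(zip(*np.where(out.significant)))
        assert flagged == {(2, 5), (5, 2)}

    def test_threshold_arithmetic_is_raw_p_vs_alpha_over_64(self):
        # 0.0009 is NOT below 0.05/64 = 0.00078125
        assert not (0.0009 < 0.05 / 64)

    def test_symmetry_and_nan_subject_drop(self, rng):
        ma = rng.normal(0.5, 1.0, size=(12, 4, 4))
        ma = (ma + ma.transpose(0, 2, 1)) / 2
        pl = rng.normal(0.0, 1.0, size=(12, 4, 4))
        pl = (pl + pl.transpose(0, 2, 1)) / 2
        ma[3, 1, 2] = ma[3, 2, 1] = np.nan
        out = grid_contrast(ma, pl, n_cells=16)
        assert np.allclose(out.t, out.t.T, equal_nan=True)
        assert out.n[1, 2] == 11 and out.n[0, 0] == 12

    def test_null_family_wise_error_controlled(self, rng):
        """Bonferroni at 0.05/64 keeps the familywise false-positive rate
        under 0.05 across null replicates (binomial envelope)."""
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(size=(12, 8, 8))
            a = (a + a.transpose(0, 2, 1)) / 2
            b = rng.normal(size=(12, 8, 8))
            b = (b + b.transpose(0, 2, 1)) / 2
            hits += grid_contrast(a, b).significant.any()
        # FWER <= 0.05; envelope: Binomial(200, 0.05) 99.9% upper bound ~ 0.11
        assert hits / reps <= 0.11


class TestChangeScores:
    def test_identical_conditions_all_zero(self):
        out = change_scores({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert out == {"a": 0.0, "b": 0.0}

    def test_unpaired_subject_dropped(self):
        out = change_scores({"a": 1.0, "b": 2.0}, {"a": 0.5, "c": 9.0})
        assert set(out) == {"a"}

    def test_linearity_delta_of_diff_equals_diff_of_deltas(self, rng):
        """Δ(high − low) per subject equals Δhigh − Δlow (algebraic identity
        of the difference scoring)."""
        subs = [f"s{i}" for i in range(10)]
        hi_ma = {s: rng.normal() for s in subs}
        hi_pl = {s: rng.normal() for s in subs}
        lo_ma = {s: rng.normal() for s in subs}
        lo_pl = {s: rng.normal() for s in subs}
        diff_ma = {s: hi_ma[s] - lo_ma[s] for s in subs}
        diff_pl = {s: hi_pl[s] - lo_pl[s] for s in subs}
        lhs = change_scores(diff_ma, diff_pl)
        d_hi = change_scores(hi_ma, hi_pl)
        d_lo = change_scores(lo_ma, lo_pl)
        for s in subs:
            assert lhs[s] == pytest.approx(d_hi[s] - d_lo[s], abs=1e-12)


class TestCorrelations:
    def test_identical_vectors_r_one(self):
        d = {"a": 1.0, "b": 2.0, "c": 3.5}
        r, _ = cs.consistency_corr(d, d)
        assert r == pytest.approx(1.0)

    def test_proportional_behavior_r_one(self):
        net = {"a": 0.1, "b": -0.2, "c": 0.3, "d": 0.05}
        dpr = {s: 2 * v for s, v in net.items()}
        r, p = cs.brain_behavior_corr(net, dpr)
        assert r == pytest.approx(1.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            cs.consistency_corr({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 3.0})

    def test_null_centered_at_zero(self, rng):
        rs = []
        for _ in range(500):
            r, _ = cs.consistency_corr(rng.normal(size=20), rng.normal(size=20))
            rs.append(r)
        assert abs(np.mean(rs)) < 0.03
        assert np.mean(np.abs(rs)) < 0.3

    def test_shared_latent_effect_recovered(self, rng):
        """A subject-level latent shared by two run types yields the strong
        cross-run consistency the analysis is designed to detect."""
        g = rng.normal(1.0, 0.7, size=40)
        rest = g + rng.normal(0, 0.7, size=40)
        doors = g + rng.normal(0, 0.7, size=40)
        r, p = cs.consistency_corr(0.15 * rest, 0.15 * doors)
        assert r > 0.4
        assert p < 0.01

    def test_coupled_generators_recover_brain_behavior_link(self):
        cfg = cs.SynthConfig(n_subjects=40, n_nodes=30, n_timepoints=120,
                             include_behavior=True, behav_coupling=1.5, seed=21)
        ds = cs.gen_condition_dataset(cfg)
        from connshift import pipeline
        conns = pipeline.dataset_connectomes(ds, "rest")
        tab = pipeline.strength_table(conns, ds.masks)
        subs, ma, pl = pipeline.paired_values(tab, "attention_diff")
        d_net = dict(zip(subs, ma - pl))
        d_beh = {s: (cs.score_gradcpt(ds.trials[(s, "MA")]).dprime
                     - cs.score_gradcpt(ds.trials[(s, "PL")]).dprime)
                 for s in subs}
        r, p = cs.brain_behavior_corr(d_net, d_beh)
        assert r > 0.3 and p < 0.05

    def test_uncoupled_generators_near_null(self):
        """Default world: the drug shifts both networks and behavior, but the
        two changes are uncorrelated across subjects (many seeds, mean |r|)."""
        rs = []
        from connshift import pipeline
        for seed in range(6):
            cfg = cs.SynthConfig(n_subjects=20, n_nodes=30, n_timepoints=120,
                                 include_behavior=True, seed=100 + seed)
            ds = cs.gen_condition_dataset(cfg)
            conns = pipeline.dataset_connectomes(ds, "rest")
            tab = pipeline.strength_table(conns, ds.masks)
            subs, ma, pl = pipeline.paired_values(tab, "attention_diff")
            d_net = dict(zip(subs, ma - pl))
            d_beh = {s: (cs.score_gradcpt(ds.trials[(s, "MA")]).dprime
                         - cs.score_gradcpt(ds.trials[(s, "PL")]).dprime)
                     for s in subs}
            rs.append(cs.brain_behavior_corr(d_net, d_beh)[0])
        assert abs(np.mean(rs)) < 0.25
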