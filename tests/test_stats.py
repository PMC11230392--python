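"""Statistical battery: oracles, examples, and simulation checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st_hyp

import foragekit.simulate as sim
import foragekit.stats as st


def brute_force_mw_p(x, y):
    """Independent enumeration oracle for the two-sided exact rank-sum p.

    Counts, over every assignment of the pooled values into groups of the
    observed sizes, how often U falls at least as deep into either tail as
    observed.  Written against raw values (not ranks) so it is independent
    of the implementation's rank-based path.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(g1, g2):
        u = 0.0
        for a in g1:
            for b in g2:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_stat(x, y)
    u_min = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = u_stat(g1, g2)
        total += 1
        if u <= u_min + 1e-9 or u >= n1 * n2 - u_min - 1e-9:
            hits += 1
    return min(1.0, hits / total)


class TestMannWhitney:
    def test_textbook_separation_example(self):
        # {1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        u, p = st.mannwhitney_exact_p([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (4, 4), (5, 3), (6, 6)])
    def test_exact_matches_brute_force_continuous(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            _, p = st.mannwhitney_exact_p(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y))

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6)])
    def test_exact_matches_brute_force_with_ties(self, n1, n2):
        rng = np.random.default_rng(n1 + 7 * n2)
        for _ in range(3):
            x = rng.integers(0, 3, n1).astype(float)
            y = rng.integers(0, 3, n2).astype(float)
            _, p = st.mannwhitney_exact_p(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y))

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 5)
        _, p = st.mannwhitney_exact_p(x, y)
        sp = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(sp))

    def test_identical_constant_groups_p_one(self):
        u, p, method = st.ranksum_test([1.0] * 4, [1.0] * 4)
        assert p == 1.0


class TestBH:
    def test_step_up_example(self):
        q = st.bh_adjust([0.001, 0.01, 0.02, 0.8])
        assert q == pytest.approx([0.004, 0.02, 0.02 * 4 / 3, 0.8], rel=1e-9)

    def test_all_ones(self):
        assert (st.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_single_p_unchanged(self):
        assert st.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.2])

    def test_matches_direct_step_up_on_random_vectors(self):
        # oracle: q_(i) = min over j>=i of p_(j) * m / j
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            order = np.argsort(p)
            ranked = p[order]
            q_sorted = np.minimum.accumulate(
                (ranked * m / np.arange(1, m + 1))[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(q_sorted, 1.0)
            assert st.bh_adjust(p) == pytest.approx(oracle)

    @given(st_hyp.lists(st_hyp.floats(min_value=0.0, max_value=1.0),
                        min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_dominance_and_monotonicity(self, pvals):
        p = np.asarray(pvals)
        q = st.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-9).all()


class TestExpressionAndDiversity:
    @pytest.fixture()
    def small_expression(self):
        assign = pd.DataFrame({
            "mouse_id": ["A"] * 10 + ["B"] * 20,
            "phase": "Foraging",
            "module": [7] * 4 + [1] * 3 + [2, 2, 3] + [5] * 20,
        })
        meta = pd.DataFrame({"mouse_id": ["A", "B"], "genotype": ["KO", "WT"],
                             "sex": ["M", "M"], "age": ["young", "young"]})
        return st.expression_table(assign, meta)

    def test_frequency_example(self, small_expression):
        a7 = small_expression.query("mouse_id == 'A' and module == 7")
        assert a7["freq"].iloc[0] == pytest.approx(0.4)

    def test_frequencies_sum_to_one(self, small_expression):
        sums = small_expression.groupby(["mouse_id", "phase"])["freq"].sum()
        assert sums.to_numpy() == pytest.approx(np.ones(len(sums)))

    def test_unknown_mouse_rejected(self):
        assign = pd.DataFrame({"mouse_id": ["Z"], "phase": ["Foraging"],
                               "module": [1]})
        meta = pd.DataFrame({"mouse_id": ["A"], "genotype": ["KO"],
                             "sex": ["M"], "age": ["young"]})
        with pytest.raises(ValueError, match="unknown mice"):
            st.expression_table(assign, meta)

    def test_diversity_examples(self, small_expression):
        div = st.module_diversity(small_expression)
        # A: 4 distinct modules over 10 excursions; B: 1 over 20
        assert div.set_index("mouse_id").loc["A", "diversity"] == pytest.approx(0.4)
        assert div.set_index("mouse_id").loc["B", "diversity"] == pytest.approx(0.05)

    def test_diversity_upper_bound(self):
        assign = pd.DataFrame({"mouse_id": "A", "phase": "Foraging",
                               "module": range(1, 13)})
        meta = pd.DataFrame({"mouse_id": ["A"], "genotype": ["KO"],
                             "sex": ["M"], "age": ["young"]})
        div = st.module_diversity(st.expression_table(assign, meta))
        assert div["diversity"].iloc[0] == 1.0


def _diversity_sim(rng, n_per_geno=15, effect_sd=0.0):
    """Mouse-level diversity data: male KO shifted by -effect_sd · SD."""
    rows = []
    i = 0
    for sex in ("M", "F"):
        for geno in ("KO", "WT"):
            for age in ("young", "aged"):
                for _ in range(n_per_geno // 2):
                    i += 1
                    mu = 0.5
                    if sex == "M" and geno == "KO":
                        mu -= effect_sd * 0.1
                    rows.append((f"M{i:03d}", geno, sex, age,
                                 rng.normal(mu, 0.1)))
    df = pd.DataFrame(rows, columns=["mouse_id", "genotype", "sex", "age",
                                     "diversity"])
    return df


class TestDiversityRegression:
    def test_planted_male_effect_power_matches_analytic(self):
        """Empirical power of the male genotype term tracks the closed-form
        noncentral-t oracle for the same contrast (treatment coding: the
        young-cell contrast at n≈7-8 per genotype×age cell)."""
        n_hit = 0
        nsim = 120
        for s in range(nsim):
            rng = np.random.default_rng(s)
            df = _diversity_sim(rng, n_per_geno=16, effect_sd=1.0)
            meta = df[["mouse_id", "genotype", "sex", "age"]]
            div = df[["mouse_id", "diversity"]].copy()
            div["phase"] = "Foraging"
            res = st.diversity_regression(div, meta)
            male_geno = [r for r in res if r.stratum == "sex=M"
                         and "genotype" in r.term and ":" not in r.term][0]
            n_hit += male_geno.p < 0.05
        # analytic oracle: two-sample t with n=8/group at d=1
        n_cell = 8
        ncp = 1.0 / np.sqrt(2 / n_cell)
        dfree = 2 * 16 - 4
        crit = ss.t.ppf(0.975, dfree)
        analytic = 1 - ss.nct.cdf(crit, dfree, ncp) + ss.nct.cdf(-crit, dfree, ncp)
        assert n_hit / nsim == pytest.approx(analytic, abs=0.12)

    def test_null_type_one_error(self):
        n_hit = 0
        nsim = 150
        for s in range(nsim):
            rng = np.random.default_rng(1000 + s)
            df = _diversity_sim(rng, n_per_geno=16, effect_sd=0.0)
            meta = df[["mouse_id", "genotype", "sex", "age"]]
            div = df[["mouse_id", "diversity"]].copy()
            div["phase"] = "Foraging"
            res = st.diversity_regression(div, meta)
            male_geno = [r for r in res if r.stratum == "sex=M"
                         and "genotype" in r.term and ":" not in r.term][0]
            n_hit += male_geno.p < 0.05
        lo, hi = ss.binom.interval(0.999, nsim, 0.05)
        assert lo <= n_hit <= hi


class TestModuleExpressionTests:
    def test_identical_frequencies_nothing_significant(self):
        meta = sim.make_group_metadata(6, ((("KO", "M", "young")),
                                           (("WT", "M", "young"))))
        rows = []
        for _, m in meta.iterrows():
            for mod in (1, 2, 3):
                rows.append((m.mouse_id, "Foraging", mod, 2, 6, 2 / 6,
                             m.genotype, m.sex, m.age))
        expr = pd.DataFrame(rows, columns=["mouse_id", "phase", "module",
                                           "count", "total", "freq",
                                           "genotype", "sex", "age"])
        res = st.test_module_expression(expr, "M", "young", "Foraging")
        assert all(r.p == 1.0 for r in res)
        assert st.count_significant(res) == 0

    def test_absent_genotype_is_error(self):
        meta = sim.make_group_metadata(4, ((("KO", "M", "young")),))
        rng = np.random.default_rng(0)
        expr = sim.simulate_module_expression(meta, 5, rng)
        with pytest.raises(ValueError, match="WT"):
            st.test_module_expression(expr, "M", "young", "Foraging")

    def test_q_at_least_p(self):
        meta = sim.make_group_metadata(8, (("KO", "M", "young"),
                                           ("WT", "M", "young")))
        expr = sim.simulate_module_expression(meta, 20, np.random.default_rng(1))
        res = st.test_module_expression(expr, "M", "young", "Foraging")
        assert all(r.q >= r.p - 1e-12 for r in res)


class TestSignificantCountModel:
    def _counts(self, values):
        rows = []
        i = 0
        for sex in ("M", "F"):
            for age in ("young", "aged"):
                for phase in ("Exploration", "Foraging"):
                    rows.append({"sex": sex, "age": age, "phase": phase,
                                 "n_significant": values[i]})
                    i += 1
        return pd.DataFrame(rows)

    def test_flat_counts_no_signal(self):
        res = st.significant_count_model(self._counts([3] * 8))
        assert res.p == 1.0

    def test_aged_foraging_excess_detected(self):
        # pattern 2,2,2,12 in both sexes: strong phase×age interaction
        res = st.significant_count_model(self._counts([2, 2, 2, 12, 2, 2, 2, 12]))
        assert res.p < 0.05

    def test_missing_level_rejected(self):
        df = self._counts([1] * 8)
        with pytest.raises(ValueError, match="levels"):
            st.significant_count_model(df[df.age == "young"])

    def test_permutation_null_uniform(self):
        # permuting cell labels under a random null: interaction p ~ U(0,1)
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1.5, 8)
        ps = []
        for _ in range(300):
            vals = rng.permutation(base)
            ps.append(st.significant_count_model(self._counts(vals)).p)
        stat, p = ss.kstest(ps, "uniform")
        assert p > 1e-3


class TestGrossRegression:
    def _gross(self, rng, n_cell=8, age_food_shift=0.0, geno_phase_dist=0.0):
        meta = sim.make_group_metadata(n_cell)
        rows = []
        for _, m in meta.iterrows():
            for phase in ("Exploration", "Foraging"):
                dist = 15000 + rng.normal(0, 1500)
                if geno_phase_dist and m.genotype == "KO" and phase == "Foraging":
                    dist += geno_phase_dist
                food = 0.6 + (age_food_shift if m.age == "aged" else 0.0)
                rows.append({
                    "mouse_id": m.mouse_id, "phase": phase,
                    "relative_time_in_center": np.clip(rng.normal(0.1, 0.03), 0, 1),
                    "distance_traveled_cm": dist,
                    "number_of_excursions": rng.poisson(25),
                    "latency_to_enter_arena_s": rng.exponential(60),
                    "food_g": max(0.0, rng.normal(food, 0.06)),
                    "sand_g": max(0.0, rng.normal(5, 1.2)),
                })
        return pd.DataFrame(rows), meta

    def test_no_effects_no_strong_calls(self):
        gross, meta = self._gross(np.random.default_rng(0))
        res = st.gross_measure_regression(gross, meta)
        main = [r for r in res if r.test == "gross_regression"]
        assert len(main) == 6 * 15          # 6 measures × 15 non-intercept terms
        # a null run should not produce overwhelming evidence anywhere
        assert min(r.p for r in main) > 1e-5

    def test_planted_age_effect_on_food_detected(self):
        # aged −30% food (SD ~10% of mean): detected essentially always
        hits = 0
        for s in range(30):
            gross, meta = self._gross(np.random.default_rng(s),
                                      n_cell=12, age_food_shift=-0.18)
            res = st.gross_measure_regression(gross, meta)
            age_terms = [r for r in res
                         if r.stratum == "measure=food_g"
                         and "age" in r.term and "genotype" not in r.term
                         and "sex" not in r.term and "phase" not in r.term]
            hits += any(r.p < 0.05 for r in age_terms)
        assert hits >= 29

    def test_planted_genotype_phase_interaction(self):
        hits = 0
        for s in range(20):
            gross, meta = self._gross(np.random.default_rng(100 + s),
                                      n_cell=12, geno_phase_dist=4000.0)
            res = st.gross_measure_regression(gross, meta)
            gp = [r for r in res
                  if r.stratum == "measure=distance_traveled_cm"
                  and "genotype" in r.term and "phase" in r.term]
            hits += any(r.p < 0.05 for r in gp)
        assert hits >= 16

    def test_missing_measure_column_rejected(self):
        gross, meta = self._gross(np.random.default_rng(0))
        with pytest.raises(ValueError, match="food_g"):
            st.gross_measure_regression(gross.drop(columns=["food_g"]), meta)


class TestSecondGuessSeries:
    def test_requires_foraging_phase(self, geometry):
        ann = pd.DataFrame({"mouse_id": "A", "phase": "Exploration",
                            "t_s": [0.0, 0.2], "x_cm": 0.0, "y_cm": 0.0,
                            "zone": "home"})
        with pytest.raises(ValueError, match="Foraging"):
            st.secondguess_series(ann, geometry)

    def _ann(self, zones, geometry, dt=0.2):
        n = len(zones)
        return pd.DataFrame({"mouse_id": "A", "phase": "Foraging",
                             "t_s": np.arange(n) * dt, "x_cm": 0.0,
                             "y_cm": 0.0, "zone": zones})

    def test_never_at_pot2_all_zero(self, geometry):
        ann = self._ann(["home"] * 9000, geometry)
        s = st.secondguess_series(ann, geometry)
        assert len(s) == 30
        assert (s["dwell_s"] == 0).all()
        assert (s["cum_dwell_s"] == 0).all()

    def test_parked_minutes_five_to_twelve(self, geometry):
        # at Pot2 exactly during [300 s, 720 s): 1-based bins 6..12 full,
        # others empty; cumulative final 420 s
        zones = np.array(["home"] * 9000, dtype=object)
        zones[1500:3600] = "Pot2"
        s = st.secondguess_series(self._ann(zones, geometry), geometry)
        s = s.set_index("bin")
        for b in range(6, 13):
            assert s.loc[b, "dwell_s"] == pytest.approx(60.0, abs=0.4)
        for b in list(range(1, 6)) + list(range(13, 31)):
            assert s.loc[b, "dwell_s"] == pytest.approx(0.0, abs=0.4)
        assert s["cum_dwell_s"].iloc[-1] == pytest.approx(420.0, abs=1.5)

    def test_bins_bounded_and_cumulative_monotone(self, geometry):
        rng = np.random.default_rng(0)
        zones = rng.choice(["home", "Pot2", "center"], 9000)
        s = st.secondguess_series(self._ann(zones, geometry), geometry)
        assert (s["dwell_s"] <= 60.0 + 1e-9).all()
        assert (s.groupby("mouse_id")["cum_dwell_s"]
                .apply(lambda c: (np.diff(c) >= -1e-9).all()).all())


class TestSecondGuessModel:
    def test_flat_null_not_significant(self):
        meta = sim.make_group_metadata(10)
        spec = sim.SecondGuessSpec(affected_groups=(),
                                   peak_amplitude_s_per_min=0.0,
                                   baseline_s_per_min=5.0)
        rng = np.random.default_rng(42)
        series = sim.simulate_secondguess_series(spec, meta, rng)
        res = st.secondguess_model(series, meta)
        assert st.secondguess_interaction_p(res, "geno_age_bin") > 0.05
        assert st.secondguess_interaction_p(res, "geno_sex_age") > 0.05

    def test_planted_peak_detected(self):
        meta = sim.make_group_metadata(12)
        spec = sim.SecondGuessSpec(affected_groups=("WT|F|aged",),
                                   peak_window_min=(5, 12),
                                   peak_amplitude_s_per_min=20.0,
                                   baseline_s_per_min=2.0)
        rng = np.random.default_rng(0)
        series = sim.simulate_secondguess_series(spec, meta, rng)
        res = st.secondguess_model(series, meta)
        assert st.secondguess_interaction_p(res, "geno_age_bin") < 0.05
        assert st.secondguess_interaction_p(res, "geno_sex_age") < 0.05


class TestPCALogit:
    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        idx = [f"M{i}" for i in range(24)]
        X = pd.DataFrame(rng.normal(0, 1, (24, 8)), index=idx)
        y = pd.Series(["KO"] * 12 + ["WT"] * 12, index=idx)
        r1 = st.pca_logit_predict(X, y)
        y_swapped = y.map({"KO": "WT", "WT": "KO"})
        r2 = st.pca_logit_predict(X, y_swapped)
        assert r1.lr_p == pytest.approx(r2.lr_p, rel=1e-6)
        assert r1.mcfadden_r2 == pytest.approx(r2.mcfadden_r2, rel=1e-6)

    def test_single_genotype_rejected(self):
        rng = np.random.default_rng(0)
        idx = [f"M{i}" for i in range(10)]
        X = pd.DataFrame(rng.normal(0, 1, (10, 4)), index=idx)
        y = pd.Series(["KO"] * 10, index=idx)
        with pytest.raises(ValueError, match="both genotypes"):
            st.pca_logit_predict(X, y)

    def test_strong_separation_handled(self):
        # a cleanly separable stratum triggers the ridge-stabilised path
        # (or a finite ordinary fit) but never an exception / infinite LR p
        rng = np.random.default_rng(1)
        idx = [f"M{i}" for i in range(20)]
        X = pd.DataFrame(rng.normal(0, 0.2, (20, 5)), index=idx)
        X.iloc[:10, 0] += 10.0
        y = pd.Series(["KO"] * 10 + ["WT"] * 10, index=idx)
        r = st.pca_logit_predict(X, y)
        assert 0 <= r.lr_p < 0.05
        assert 0 <= r.mcfadden_r2 <= 1.0
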