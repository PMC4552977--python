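"""Breeding-scheme engine: designs, selection, mating plans, full cycles."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrgsim.schemes import (
    SchemeConfig,
    design_progeny_test,
    make_within_pop_matings,
    measure_hybrid_production,
    run_scheme,
    scheme_years,
    select_parents,
    select_snp_panel,
)


class TestSchemeConfig:
    def test_rrs_constraints(self):
        with pytest.raises(ValueError):
            SchemeConfig(strategy="RRS", pattern="GMGM")
        with pytest.raises(ValueError):
            SchemeConfig(strategy="RRS", n_candidates=300)
        with pytest.raises(ValueError):
            SchemeConfig(strategy="RRS", n_genotyped_hybrids=300)

    def test_hyb_requires_genotyped_hybrids(self):
        with pytest.raises(ValueError):
            SchemeConfig(strategy="RRGS_HYB", n_genotyped_hybrids=0)

    @pytest.mark.parametrize(
        "pattern,total", [("GGGG", 80.0), ("GMGM", 52.0), ("GMMM", 38.0)]
    )
    def test_years_accounting(self, pattern, total):
        assert scheme_years(pattern) == total
        cfg = SchemeConfig(strategy="RRGS_PAR", pattern=pattern)
        assert sum(cfg.years_per_cycle()) == total


class TestProgenyTestDesign:
    def test_study_design_balance(self, rng):
        """120 + 120 parents, 300 crosses: usage counts are only 2 or 3,
        with exactly 60 parents used three times per population."""
        plan = design_progeny_test(120, 120, 300, rng)
        assert plan.shape == (300, 2)
        for col in (0, 1):
            usage = np.bincount(plan[:, col], minlength=120)
            assert set(usage.tolist()) == {2, 3}
            assert np.sum(usage == 3) == 60 and np.sum(usage == 2) == 60
        # no duplicate pair
        keys = plan[:, 0] * 120 + plan[:, 1]
        assert np.unique(keys).size == 300

    def test_two_by_two_full_factorial(self, rng):
        plan = design_progeny_test(2, 2, 4, rng)
        assert sorted(map(tuple, plan.tolist())) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_infeasible_rejected(self, rng):
        with pytest.raises(ValueError):
            design_progeny_test(2, 2, 5, rng)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 30))
    def test_no_duplicate_pairs_property(self, seed):
        rng = np.random.default_rng(seed)
        plan = design_progeny_test(10, 12, 40, rng)
        keys = plan[:, 0] * 12 + plan[:, 1]
        assert np.unique(keys).size == 40


class TestSelectParents:
    def test_dominant_candidate_always_selected(self, rng):
        g1 = np.zeros((5, 2))
        g1[2] = [2.0, 2.0]  # dominates on both traits
        g2 = np.zeros((5, 2))
        sel1, _ = select_parents(g1, g2, np.array([15.0, 15.0]), 2, rng)
        assert 2 in sel1

    def test_matches_brute_force_on_three_candidates(self, rng):
        g1 = np.array([[0.5, -0.2], [0.1, 0.4], [-0.3, 0.6]])
        g2 = np.array([[0.2, 0.1], [-0.1, 0.3], [0.4, -0.2]])
        means = np.array([15.0, 15.0])
        opp = g2.mean(axis=0)
        scores = [
            (means[0] + g1[i, 0] + opp[0]) * (means[1] + g1[i, 1] + opp[1])
            for i in range(3)
        ]
        sel1, _ = select_parents(g1, g2, means, 1, rng)
        assert sel1[0] == int(np.argmax(scores))

    def test_identical_candidates_give_seeded_subset(self):
        g = np.zeros((6, 2))
        s1 = select_parents(g, g, np.array([15.0, 15.0]), 3,
                            np.random.default_rng(4))
        s2 = select_parents(g, g, np.array([15.0, 15.0]), 3,
                            np.random.default_rng(4))
        assert np.array_equal(s1[0], s2[0])

    def test_too_few_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_parents(np.zeros((3, 2)), np.zeros((3, 2)),
                           np.array([15.0, 15.0]), 5, rng)


class TestWithinPopMatings:
    def test_study_diallel_cross_count(self, rng):
        """20 parents, 80% of the selfing half diallel: 168 crosses."""
        plan = make_within_pop_matings(20, 0.8, 300, rng)
        assert plan.shape[0] == 168
        assert plan[:, 2].sum() == 300
        # one or two offspring per cross when producing 300
        assert set(plan[:, 2].tolist()) <= {1, 2}

    def test_full_diallel_is_210(self, rng):
        plan = make_within_pop_matings(20, 1.0, 210, rng)
        assert plan.shape[0] == 210

    def test_two_parent_enumeration(self, rng):
        plan = make_within_pop_matings(2, 1.0, 4, rng)
        crosses = sorted(map(tuple, plan[:, :2].tolist()))
        assert crosses == [(0, 0), (0, 1), (1, 1)]
        assert plan[:, 2].sum() == 4
        assert plan[:, 2].max() - plan[:, 2].min() <= 1

    def test_fewer_offspring_than_crosses(self, rng):
        plan = make_within_pop_matings(20, 0.8, 120, rng)
        assert plan[:, 2].sum() == 120
        assert set(plan[:, 2].tolist()) == {1}  # zero rows dropped

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 20), n=st.sampled_from([4, 8, 20]))
    def test_per_parent_participation_near_equal(self, seed, n):
        rng = np.random.default_rng(seed)
        plan = make_within_pop_matings(n, 0.8, 2 * n, rng)
        usage = np.zeros(n, dtype=int)
        for a, b, _ in plan:
            usage[a] += 1
            usage[b] += 1
        assert usage.max() - usage.min() <= 2


class TestSnpPanel:
    def test_monomorphic_loci_rejected(self, rng):
        with pytest.raises(ValueError):
            select_snp_panel(np.full((6, 10), 2), 0.04, 5, rng)

    def test_zero_threshold_keeps_segregating(self, rng):
        dos = np.zeros((4, 6), dtype=int)
        dos[0, [1, 3]] = 1
        panel = select_snp_panel(dos, 0.0, 10, rng)
        assert panel.tolist() == [1, 3]

    def test_hand_computed_eligibility(self, rng):
        # frequencies 0.05 and 0.25 on 10 individuals
        dos = np.zeros((10, 3), dtype=int)
        dos[0, 0] = 1  # p = 0.05 -> eligible at maf > 0.04
        dos[:5, 1] = 1  # p = 0.25 -> eligible
        panel = select_snp_panel(dos, 0.04, 10, rng)
        assert panel.tolist() == [0, 1]
        panel2 = select_snp_panel(dos, 0.10, 10, rng)
        assert panel2.tolist() == [1]


class TestHybridProduction:
    def test_all_zero_tbv_gives_225(self):
        v = measure_hybrid_production(
            np.zeros((3, 2)), np.zeros((4, 2)), np.array([15.0, 15.0])
        )
        assert v == pytest.approx(225.0)

    def test_two_by_two_hand_computation(self):
        t1 = np.array([[2.0, 0.0], [0.0, 2.0]])
        t2 = np.array([[-2.0, 0.0], [0.0, -2.0]])
        means = np.array([15.0, 15.0])
        vals = []
        for i in range(2):
            for j in range(2):
                bw = 15 + 0.5 * (t1[i, 0] + t2[j, 0])
                bn = 15 + 0.5 * (t1[i, 1] + t2[j, 1])
                vals.append(bw * bn)
        assert measure_hybrid_production(t1, t2, means) == pytest.approx(
            np.mean(vals)
        )
        # explicit pair list
        pairs = np.array([[0, 0], [1, 1]])
        assert measure_hybrid_production(t1, t2, means, pairs) == pytest.approx(
            (vals[0] + vals[3]) / 2
        )


@pytest.fixture(scope="module")
def runs(tiny_fixture):
    """One reduced run per strategy on the tiny founders."""
    out = {}
    for key, kw in {
        "RRS": dict(),
        "PAR": dict(strategy="RRGS_PAR", pattern="GMGM"),
        "HYB": dict(strategy="RRGS_HYB", pattern="GMMM",
                    n_genotyped_hybrids=30),
    }.items():
        cfg = tiny_fixture.scheme(**kw)
        out[key] = run_scheme(
            cfg, copy.deepcopy(tiny_fixture.founders),
            np.random.default_rng(7),
        )
    return out


class TestFullScheme:

    def test_years_and_generations(self, runs):
        assert runs["RRS"].total_years == 80.0
        assert runs["PAR"].total_years == 52.0
        assert runs["HYB"].total_years == 38.0
        for s in runs.values():
            assert [r.generation for r in s.records] == [0, 1, 2, 3, 4]
            years = [r.years_elapsed for r in s.records]
            assert all(b > a for a, b in zip(years, years[1:]))

    def test_baseline_response_zero(self, runs):
        for s in runs.values():
            assert s.table["response_pct"].iloc[0] == 0.0

    def test_population_sizes_conserved(self, runs, tiny_fixture):
        for s in runs.values():
            for rec in s.records:
                assert np.isfinite(rec.hybrid_production)

    def test_accuracy_progeny_tested_beats_marker_only(self, runs):
        """Calibration-generation accuracy exceeds the accuracy of the
        following marker-only generation (qualitative accuracy drop)."""
        s = runs["HYB"]
        acc = [np.nanmean(list(r.accuracy.values())) for r in s.records[1:]]
        assert acc[0] > acc[1]

    def test_inbreeding_non_decreasing(self, runs):
        for s in runs.values():
            for pop in ("Deli", "LaMe"):
                F = [r.mean_inbreeding[pop] for r in s.records]
                assert F[-1] >= F[0]

    def test_additive_variance_depletes(self, runs):
        """Selection plus drift deplete additive variance over four cycles
        (checked on the pooled trait/population average)."""
        for s in runs.values():
            v0 = np.mean(list(s.records[0].additive_variance.values()))
            v4 = np.mean(list(s.records[-1].additive_variance.values()))
            assert v4 < v0

    def test_determinism(self, tiny_fixture):
        cfg = tiny_fixture.scheme()
        s1 = run_scheme(cfg, copy.deepcopy(tiny_fixture.founders),
                        np.random.default_rng(3), n_cycles=2)
        s2 = run_scheme(cfg, copy.deepcopy(tiny_fixture.founders),
                        np.random.default_rng(3), n_cycles=2)
        assert s1.table.equals(s2.table)
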