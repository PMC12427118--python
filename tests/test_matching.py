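"""Match-score, randomized nulls, Cohen's d, Wilcoxon and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nucsteric.matching import (
    ThresholdPair,
    classify_expression,
    cohens_d,
    effect_size_class,
    map_accessibility,
    match_score,
    randomize_methylation,
    sliding_match,
    stratify,
    wilcoxon_test,
)

C5M0 = ThresholdPair(5, 0)


class TestThresholdPair:
    def test_label(self):
        assert C5M0.label == "c5m0"
        assert ThresholdPair(20, 10).label == "c20m10"


class TestMapAccessibility:
    def test_offset_convention(self):
        clash = np.arange(136.0)
        pairs = map_accessibility(1000, clash, [1000, 1135], [50.0, 60.0])
        assert pairs == [(50.0, 0.0), (60.0, 135.0)]

    def test_reversed_orientation(self):
        clash = np.arange(136.0)
        pairs = map_accessibility(1000, clash, [1000], [50.0], orientation="-")
        assert pairs == [(50.0, 135.0)]

    def test_outside_window_excluded(self):
        clash = np.arange(136.0)
        assert map_accessibility(1000, clash, [999, 2000], [1.0, 2.0]) == []


class TestMatchScore:
    def test_all_methylated_accessible(self):
        assert match_score([(50, 2), (80, 4)], C5M0) == 1.0

    def test_unmethylated_but_accessible_is_mismatch(self):
        assert match_score([(0, 2)], C5M0) == 0.0

    def test_four_branch_enumeration(self):
        # (meth,acc)=1, (unmeth,inacc)=1, (unmeth,acc)=0, (meth,inacc)=0
        assert match_score([(50, 2), (0, 40), (0, 2), (50, 40)], C5M0) == 0.5

    def test_boundary_semantics(self):
        # m == m_thres counts unmethylated; c == c_thres counts tolerated
        thr = ThresholdPair(5, 10)
        assert match_score([(10, 5)], thr) == 0.0  # unmethylated & tolerated
        assert match_score([(10, 5.01)], thr) == 1.0  # unmethylated & not tolerated

    def test_empty_window_undefined(self):
        with pytest.raises(ValueError):
            match_score([], C5M0)

    @given(
        ms=st.lists(st.floats(0, 100), min_size=1, max_size=30),
        cs=st.integers(0, 10_000),
    )
    def test_complement_property(self, ms, cs):
        """score(M) + score(not-M) = 1: inverting the agreement indicator
        complements the score."""
        rng = np.random.default_rng(cs)
        pairs = [(m, float(c)) for m, c in zip(ms, rng.uniform(0, 100, len(ms)))]
        s = match_score(pairs, C5M0)
        arr = np.asarray(pairs)
        inv = np.mean(
            ~(((arr[:, 0] > 0) & (arr[:, 1] <= 5)) | ((arr[:, 0] <= 0) & (arr[:, 1] > 5)))
        )
        assert np.isclose(s + inv, 1.0)


def _ndr(start, end, kind="HNDR"):
    return pd.DataFrame([{"chrom": "c", "start": start, "end": end, "kind": kind}])


def _region(start, end):
    return pd.DataFrame(
        [{"chrom": "c", "start": start, "end": end, "region_class": "promoter_tss",
          "gene_id": "g", "strand": "+"}]
    )


def _sites(positions, levels):
    return pd.DataFrame(
        {"chrom": "c", "start": positions, "end": np.asarray(positions) + 1,
         "level": levels, "n_meth": 1, "n_total": 1}
    )


class TestSlidingMatch:
    def test_short_ndr_yields_no_windows(self):
        out = sliding_match(
            _ndr(0, 100), _region(0, 1000), _sites([50], [80.0]),
            np.zeros(136), C5M0,
        )
        assert len(out) == 0

    def test_exact_fit_single_window(self):
        out = sliding_match(
            _ndr(100, 236), _region(0, 1000), _sites([110, 150, 200], [80.0, 0.0, 80.0]),
            np.zeros(136), C5M0,
        )
        assert len(out) == 1
        assert out.iloc[0].n_cpgs == 3
        assert out.iloc[0].window_start == 100

    def test_window_count_enumeration(self):
        # 200-bp NDR, 136-bp windows, step 1 -> 65 placements
        sites = _sites(list(range(300, 500, 10)), [80.0] * 20)
        out = sliding_match(
            _ndr(300, 500), _region(0, 1000), sites, np.zeros(136), C5M0
        )
        assert len(out) == 65

    def test_registers_agree_at_zero_window_start(self):
        clash = np.linspace(0, 100, 136)
        sites = _sites([0, 50, 135], [80.0, 80.0, 0.0])
        genomic = sliding_match(
            _ndr(0, 136), _region(0, 500), sites, clash, C5M0, register="genomic"
        )
        window = sliding_match(
            _ndr(0, 136), _region(0, 500), sites, clash, C5M0, register="window"
        )
        assert np.isclose(genomic.iloc[0].score, window.iloc[0].score)


class TestRandomize:
    def test_single_site_unchanged(self):
        s = _sites([5], [42.0])
        out = randomize_methylation(s, seed=0)
        assert out.loc[0, "level"] == 42.0

    def test_level_multiset_preserved(self):
        rng = np.random.default_rng(1)
        s = _sites(np.arange(500), rng.uniform(0, 100, 500))
        out = randomize_methylation(s, seed=3)
        assert sorted(out["level"]) == pytest.approx(sorted(s["level"]))
        assert (out["start"] == s["start"]).all()
        assert not (out["level"] == s["level"]).all()

    def test_deterministic_per_seed(self):
        s = _sites(np.arange(100), np.arange(100, dtype=float))
        a = randomize_methylation(s, seed=9)["level"].tolist()
        b = randomize_methylation(s, seed=9)["level"].tolist()
        c = randomize_methylation(s, seed=10)["level"].tolist()
        assert a == b and a != c

    def test_shuffled_mean_score_matches_independence_expectation(self):
        """With marginal methylated fraction p and accessible fraction q,
        the expected shuffled match-score is p*q + (1-p)*(1-q)."""
        rng = np.random.default_rng(4)
        n = 4000
        positions = np.arange(n) * 5
        p = 0.3
        levels = np.where(rng.random(n) < p, 80.0, 0.0)
        clash = np.where(rng.random(136) < 0.4, 0.0, 50.0)  # q = P(c<=5) ~ 0.4
        q = float(np.mean(clash <= 5.0))
        sites = randomize_methylation(_sites(positions, levels), seed=5)
        out = sliding_match(
            _ndr(0, n * 5), _region(0, n * 5), sites, clash, C5M0
        )
        expected = p * q + (1 - p) * (1 - q)
        assert abs(out["score"].mean() - expected) < 0.02


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_printed_formula_unit_case(self):
        # means 1 and 0, both sample sd 1 -> d = 1
        a = [0.0, 1.0, 2.0]
        b = [-1.0, 0.0, 1.0]
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_monte_carlo_known_population_d(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.8, 0.1, 10_000)
        b = rng.normal(0.5, 0.1, 10_000)
        assert cohens_d(a, b) == pytest.approx(3.0, abs=0.1)

    def test_antisymmetry_and_affine_invariance(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=50), rng.normal(1.0, 2.0, size=60)
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d)
        assert cohens_d(3 * a + 5, 3 * b + 5) == pytest.approx(d)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestWilcoxon:
    def test_identical_singletons(self):
        assert wilcoxon_test([1.0], [1.0]) == 1.0

    def test_exact_small_sample(self):
        # fully separated 3-vs-3: exact two-sided p = 2/20 = 0.1
        assert wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        assert wilcoxon_test(rng.normal(1, 1, 500), rng.normal(0, 1, 500)) < 1e-10


class TestStratify:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.85, "large"), (0.8, "large"), (0.79, "medium"), (0.5, "medium"),
         (0.2, "small"), (0.1, "negligible"), (-0.9, "large")],
    )
    def test_effect_size_bins(self, d, expected):
        assert effect_size_class(d) == expected

    def test_small_strata_reported_na(self):
        m = pd.DataFrame(
            {
                "region_class": ["promoter_tss"] * 3,
                "ndr_kind": ["HNDR"] * 3,
                "threshold": ["c5m0"] * 3,
                "n_cpgs": [12, 12, 12],
                "score": [0.9, 0.8, 0.5],
                "data_kind": ["experimental", "experimental", "randomized"],
            }
        )
        out = stratify(m, ncpg_bins=[("10-20", 10, 20)])
        assert out["size_class"].iloc[0] == "NA"
        assert np.isnan(out["cohens_d"].iloc[0])
        assert out["n_rand"].iloc[0] == 1


class TestExpression:
    def test_threshold_is_strictly_positive(self):
        tpm = pd.DataFrame({"gene_id": ["a", "b", "c"], "tpm": [0.01, 0.0, 7.0]})
        cls = classify_expression(tpm)
        assert cls.tolist() == ["expressed", "non_expressed", "expressed"]

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            classify_expression(pd.DataFrame({"gene_id": ["a"], "tpm": [-1.0]}))

    def test_missing_gene_maps_to_unknown_in_matches(self, effect_matches):
        assert set(effect_matches["expression_class"]) <= {"expressed", "non_expressed", "unknown"}


class TestParameterRecovery:
    def test_coupled_data_separates_hndr_from_lndr(self, effect_matches):
        """At coupling 0.8, HNDR windows with 10-20 CpGs show a large
        standardized separation from the shuffled null, clearly above
        the LNDR (negative-control) strata."""
        summ = stratify(effect_matches, ncpg_bins=[("10-20", 10, 20)])
        summ = summ[summ["expression_class"] == "expressed"].set_index(
            ["region_class", "ndr_kind"]
        )
        d_hndr = summ.loc[("promoter_tss", "HNDR"), "cohens_d"]
        assert d_hndr >= 0.8
        if ("promoter_tss", "LNDR") in summ.index:
            assert d_hndr > summ.loc[("promoter_tss", "LNDR"), "cohens_d"]

    def test_window_register_is_a_null(self, sim_bundle, clash_profile):
        """Scoring each window under its own assumed nucleosome origin
        erases the planted coupling (shift-averaged agreement equals the
        independence expectation): the effect collapses toward zero.

        This is the documented negative control for the register choice.
        """
        from nucsteric.matching import matched_experiment

        matches = matched_experiment(
            sim_bundle["ndrs"].query("chrom == 'chrS'"),
            sim_bundle["regions"][sim_bundle["regions"].region_class == "promoter_tss"],
            sim_bundle["hcg"],
            clash_profile,
            thresholds=[C5M0],
            seed=21,
            register="window",
            step=7,  # thinned placements; the register property is shift-based
        )
        summ = stratify(matches, ncpg_bins=[("10-20", 10, 20)])
        d = summ.set_index("ndr_kind")["cohens_d"]
        assert abs(d.get("HNDR", 0.0)) < 0.35
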