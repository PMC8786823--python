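"""obs/exp enrichment, position variance, context profiles and CpX summary."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tetflank import flank_profiles as fp
from tetflank import synthetic_library as sl
from tetflank.kinetics_ode import ODEParameters, integrate_exact

from conftest import pwm_rate_fn, records_from_truth


def _records(contexts, calls, site_class="CpG"):
    return pd.DataFrame(
        {
            "molecule_id": [f"m{i}" for i in range(len(contexts))],
            "context": contexts,
            "x_base": site_class[-1],
            "site_class": site_class,
            "call": calls,
        }
    )


@pytest.fixture(scope="module")
def biased_library():
    """Oxidation strongly favoring A at the -1 flank position."""
    lib = sl.generate_library(20_000, "mCpG", seed=100)
    rate_fn = pwm_rate_fn({-1: {"A": 4.0, "G": 0.25}}, base_rate=0.3)
    model = sl.GroundTruthModel("mCpG", rate_fn)
    return sl.simulate_oxidation(lib, model, 2.0, seed=101)


class TestObsExp:
    def test_identical_pools_give_unity(self):
        ctx = ["ACGTACGTACGTACGTACGT"] * 8
        rec = _records(ctx, ["oxidized"] * 4 + ["unconverted"] * 4)
        table = fp.obs_exp(rec)
        assert np.allclose(table.ratio.fillna(1.0).to_numpy(), 1.0)

    def test_pure_base_against_uniform_reference_gives_four(self):
        # all product molecules carry A at -1; reference uniform there
        contexts = []
        calls = []
        for i, b in enumerate("ACGT"):
            ctx = "A" * 9 + b + "A" * 10
            contexts += [ctx] * 10
            calls += (["oxidized"] if b == "A" else ["unconverted"]) * 10
        table = fp.obs_exp(_records(contexts, calls))
        assert table.ratio.loc[-1, "A"] == pytest.approx(4.0)

    def test_empty_product_pool_raises(self):
        rec = _records(["A" * 20], ["unconverted"])
        with pytest.raises(ValueError, match="empty product pool"):
            fp.obs_exp(rec)

    def test_matches_brute_force_enumeration(self, biased_library):
        """Independent oracle: direct counting over the ground-truth states."""
        rec = records_from_truth(biased_library)
        table = fp.obs_exp(rec)
        oxidized = [m for m in biased_library if m.current_state in ("5fC", "5caC")]
        positions = fp.position_labels(10)
        for pos_idx, pos in enumerate(positions):
            for b in "ACGT":
                obs = sum(m.context[pos_idx] == b for m in oxidized) / len(oxidized)
                exp = sum(m.context[pos_idx] == b for m in biased_library) / len(biased_library)
                assert abs(table.ratio.loc[pos, b] - obs / exp) < 1e-12

    def test_conservation_identity(self, biased_library):
        # sum_b expected_freq(b) * obsexp(b) = 1 at every position
        table = fp.obs_exp(records_from_truth(biased_library))
        total = (table.expected_freq * table.ratio).sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_uniform_expected_flag(self, biased_library):
        table = fp.obs_exp(records_from_truth(biased_library), expected="uniform")
        assert np.allclose(table.expected_freq.to_numpy(), 0.25)


class TestPositionVariance:
    def test_flat_table_flagged_and_unscaled(self):
        ctx = ["ACGTACGTACGTACGTACGT"] * 8
        table = fp.obs_exp(_records(ctx, ["oxidized"] * 4 + ["unconverted"] * 4))
        pv = fp.position_variance(table)
        assert pv.attrs["flat"] and (pv["raw"] == 0).all()

    def test_single_position_arithmetic(self):
        # obs/exp (2, 0.5, 0.75, 0.75) -> (1)^2+(0.5)^2+(0.25)^2+(0.25)^2
        table = fp.ObsExpTable(
            ratio=pd.DataFrame([[2.0, 0.5, 0.75, 0.75]], index=[-1], columns=list("ACGT")),
            observed_freq=None,
            expected_freq=None,
            n_product=1,
            n_reference=1,
        )
        pv = fp.position_variance(table)
        assert pv.loc[-1, "raw"] == pytest.approx(1.375)
        assert pv.loc[-1, "scaled"] == pytest.approx(1.0)

    def test_planted_minus_one_preference_dominates(self, biased_library):
        table = fp.obs_exp(records_from_truth(biased_library))
        pv = fp.position_variance(table)
        assert pv["scaled"].idxmax() == -1
        assert pv.loc[-1, "scaled"] == pytest.approx(1.0)
        assert (pv.drop(index=-1)["scaled"] < 0.5).all()


class TestContextAverage:
    def test_all_oxidized_gives_unity_everywhere_observed(self):
        lib = sl.generate_library(3000, "mCpG", seed=110)
        rec = records_from_truth(lib)
        rec["call"] = "oxidized"
        prof = fp.context_average(rec, low_coverage_floor=1)
        observed = prof[prof["n"] > 0]
        assert (observed["value"] == 1.0).all()

    def test_permutation_invariance(self, biased_library):
        rec = records_from_truth(biased_library)
        shuffled = rec.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = fp.context_average(rec)
        b = fp.context_average(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_matches_matrix_exponential_oracle(self):
        """Per-context oxidized fraction vs the deterministic four-species
        solution, for a rate function that depends on the context."""
        n = 120_000
        t = 2.0
        lib = sl.generate_library(n, "mCpG", seed=111)
        rate_fn = pwm_rate_fn({-1: {"A": 2.0, "G": 0.5}}, base_rate=0.3)
        model = sl.GroundTruthModel("mCpG", rate_fn)
        out = sl.simulate_oxidation(lib, model, t, seed=112)
        prof = fp.context_average(records_from_truth(out), low_coverage_floor=20)
        # check a handful of contexts against the oracle
        for ctx in ("AACGAA", "TGCGTT", "CACGGC", "GGCGCC"):
            flank = "A" * 8 + ctx[:2] + ctx[4:] + "A" * 8  # any flank with the right -2..+2
            k1, k2, k12, k3 = rate_fn(flank)
            exact = integrate_exact(
                ODEParameters(k1=k1, k2=k2, k12=k12, k3=k3), [1, 0, 0, 0], [t]
            ).iloc[0]
            expect = exact["5fC"] + exact["5caC"]
            n_ctx = prof.loc[ctx, "n"]
            se = np.sqrt(expect * (1 - expect) / n_ctx)
            assert abs(prof.loc[ctx, "value"] - expect) < 3.5 * se, ctx

    def test_independent_seeds_correlate(self):
        """Repeat-experiment reproducibility of the 256-context profile."""
        rate_fn = pwm_rate_fn({-1: {"A": 3.0, "G": 0.3}, 1: {"C": 0.5}}, base_rate=0.3)
        model = sl.GroundTruthModel("mCpG", rate_fn)
        profs = []
        for seed in (120, 121):
            lib = sl.generate_library(100_000, "mCpG", seed=seed)
            out = sl.simulate_oxidation(lib, model, 2.0, seed=seed + 10)
            profs.append(fp.context_average(records_from_truth(out)))
        r = fp.profile_correlation({"a": profs[0], "b": profs[1]}).loc["a", "b"]
        assert r > 0.95


class TestRankAndExtremes:
    def test_strictly_decreasing_profile_ranks_in_order(self):
        contexts = fp.all_contexts("G")
        prof = pd.DataFrame({"value": np.linspace(1, 0, 256)}, index=contexts)
        assert fp.rank_context(prof, contexts[0]) == 1
        assert fp.rank_context(prof, contexts[255]) == 256

    def test_all_equal_profile_every_rank_one(self):
        prof = pd.DataFrame({"value": 0.5}, index=fp.all_contexts("G"))
        assert fp.rank_context(prof, "AACGAA") == 1
        assert fp.rank_context(prof, "TTCGTT") == 1

    def test_planted_best_context_ranks_first(self, biased_library):
        prof = fp.context_average(records_from_truth(biased_library), low_coverage_floor=1)
        best = prof["value"].idxmax()
        assert fp.rank_context(prof, best) == 1

    def test_single_top_context_gives_one_hot_rows(self):
        prof = pd.DataFrame({"value": np.linspace(1, 0, 256)}, index=fp.all_contexts("G"))
        top, _, mat, _ = fp.extreme_subsets(prof, n_top=1, n_bottom=1)
        assert top == ["AACGAA"]
        for pos, base in zip([-2, -1, 1, 2], "AAAA"):
            assert mat.loc[pos, base] == 1.0

    def test_logo_rows_sum_to_one(self, biased_library):
        prof = fp.context_average(records_from_truth(biased_library), low_coverage_floor=1)
        _, _, top_mat, bottom_mat = fp.extreme_subsets(prof, 10, 10)
        assert np.allclose(top_mat.sum(axis=1), 1.0)
        assert np.allclose(bottom_mat.sum(axis=1), 1.0)

    def test_planted_preference_dominates_top_subset(self, biased_library):
        prof = fp.context_average(records_from_truth(biased_library), low_coverage_floor=1)
        _, _, top_mat, bottom_mat = fp.extreme_subsets(prof, 10, 10)
        assert top_mat.loc[-1].idxmax() == "A"
        assert bottom_mat.loc[-1].idxmax() == "G"

    def test_oversized_subsets_rejected(self):
        prof = pd.DataFrame({"value": 0.5}, index=fp.all_contexts("G"))
        with pytest.raises(ValueError):
            fp.extreme_subsets(prof, 200, 100)


class TestProfileCorrelation:
    def test_identity_negation_and_independent_formula(self):
        rng = np.random.default_rng(3)
        v = pd.Series(rng.random(256), index=fp.all_contexts("G"))
        corr = fp.profile_correlation({"a": v, "b": v, "neg": -v})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)
        w = pd.Series(rng.random(256), index=v.index)
        corr2 = fp.profile_correlation({"v": v, "w": w})
        # independent covariance computation
        manual = np.mean((v - v.mean()) * (w - w.mean())) / (v.std(ddof=0) * w.std(ddof=0))
        assert corr2.loc["v", "w"] == pytest.approx(manual, abs=1e-12)

    def test_pairwise_null_exclusion(self):
        v = pd.Series([1.0, 2.0, 3.0, np.nan], index=list("abcd"))
        w = pd.Series([1.0, 2.0, 3.0, 100.0], index=list("abcd"))
        corr = fp.profile_correlation({"v": v, "w": w})
        assert corr.loc["v", "w"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def cpn_records():
    # competitive CpN reaction; CpG fastest, CpT nearly inert
    lib = sl.generate_library(40_000, "mCpX", seed=130)
    class_rate = {"G": 0.6, "A": 0.25, "C": 0.18, "T": 0.01}

    def rate_fn(context):
        k1 = class_rate[context[-1]]  # CpX key carries the X base last
        return (k1, 0.6 * k1, 0.15 * k1, 0.3 * k1)

    model = sl.GroundTruthModel("mCpX", rate_fn)
    out = sl.simulate_oxidation(lib, model, 2.0, seed=131)
    return records_from_truth(out)


class TestCpxSummary:
    def test_class_ordering_follows_planted_rates(self, cpn_records):
        summary = fp.cpx_summary(cpn_records)
        order = list(summary.relative_activity.index)
        assert order[0] == "CpG"
        assert summary.relative_activity.iloc[0] == pytest.approx(100.0)
        assert order[-1] == "CpT"
        assert set(order[1:3]) == {"CpA", "CpC"}

    def test_relative_activities_reproduce_rate_ratios(self, cpn_records):
        summary = fp.cpx_summary(cpn_records)
        # oxidized fraction is monotone in rate; CpA/CpC ratio of activities
        # should fall between their rate ratio and 1 (saturation compresses)
        rel = summary.relative_activity
        assert 0.25 / 0.6 * 0.5 < rel["CpA"] / 100.0 < 1.0
        assert rel["CpA"] > rel["CpC"] > rel["CpT"]

    def test_low_activity_class_excluded_from_profiles(self, cpn_records):
        summary = fp.cpx_summary(cpn_records)
        assert "CpT" in summary.excluded_classes
        assert "CpT" not in summary.profiles
        assert set(summary.histogram.columns) <= {"CpG", "CpA", "CpC"}

    def test_histogram_counts_contexts(self, cpn_records):
        summary = fp.cpx_summary(cpn_records)
        for cls, prof in summary.profiles.items():
            assert summary.histogram[cls].sum() == prof["value"].notna().sum()
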