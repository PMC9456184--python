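import numpy as np
import pandas as pd
import pytest

from lncsponge.expression import (
    bh_adjust,
    classify_de,
    compute_fpkm,
    estimate_common_dispersion,
    expression_filter,
    nb_exact_test,
    tmm_factors,
)
from lncsponge.seqio import TranscriptRecord
from lncsponge.simulate import SimulationConfig, make_filter_fixture, simulate_counts

from oracles import bh_oracle, tmm_oracle


def _sample_table(n_unfed=3, n_fed=3, timepoints=None):
    rows = []
    for i in range(n_unfed):
        rows.append({"sample_id": f"u{i}", "tissue": "midgut",
                     "condition": "unfed", "timepoint": pd.NA})
    for i in range(n_fed):
        tp = timepoints[i % len(timepoints)] if timepoints else pd.NA
        rows.append({"sample_id": f"f{i}", "tissue": "midgut",
                     "condition": "fed", "timepoint": tp})
    return pd.DataFrame(rows).set_index("sample_id")


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10.0, 999990.0]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["a", "s"] == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (20, 4)).astype(float),
                              index=[f"t{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 2000, 20), index=counts.index)
        doubled = counts.copy()
        doubled["a"] *= 2
        pd.testing.assert_series_equal(
            compute_fpkm(counts, lengths)["a"], compute_fpkm(doubled, lengths)["a"]
        )

    def test_formula_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, (20, 4)).astype(float),
                              index=[f"t{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 2000, 20), index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        for t in counts.index:
            for s in counts.columns:
                expected = (counts.loc[t, s] / (lengths[t] / 1000)
                            / (counts[s].sum() / 1e6))
                assert fpkm.loc[t, s] == pytest.approx(expected)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s": [0.0]}, index=["a"])
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(counts, pd.Series({"a": 100}))


class TestExpressionFilter:
    def test_boundary_inclusive(self):
        st = _sample_table(2, 2)
        fpkm = pd.DataFrame([[5.0, 5.0, 0.0, 0.0]], index=["t"],
                            columns=st.index)
        assert expression_filter(fpkm, st) == ["t"]

    def test_just_below_everywhere_dropped(self):
        st = _sample_table(2, 2)
        fpkm = pd.DataFrame([[4.9, 100.0, 4.9, 100.0]], index=["t"],
                            columns=st.index)
        assert expression_filter(fpkm, st) == []

    def test_fed_timepoints_are_separate_groups(self):
        st = _sample_table(2, 4, timepoints=["24h", "72h"])
        # passes only within the 24h group
        vals = {"u0": 0.0, "u1": 0.0, "f0": 9.0, "f1": 0.0, "f2": 9.0, "f3": 0.0}
        fpkm = pd.DataFrame([vals], index=["t"])[st.index.tolist()]
        assert expression_filter(fpkm, st) == ["t"]

    def test_planted_pass_fail_recount(self):
        st = _sample_table(3, 6, timepoints=["24h", "72h"])
        fpkm, pass_ids = make_filter_fixture(30, 70, st, seed=5)
        assert sorted(expression_filter(fpkm, st)) == sorted(pass_ids)


class TestTmm:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10.0, 20, 30], "b": [10.0, 20, 30]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_constant_multiple_absorbed_by_library_size(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(100, 200).astype(float) + 1
        counts = pd.DataFrame({"a": a, "b": 3 * a})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_matches_stepwise_oracle(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(200, 4)).astype(float),
            columns=list("abcd"),
        )
        got = tmm_factors(counts)
        expected = tmm_oracle(counts.to_numpy(), list(counts.columns))
        for s in counts.columns:
            assert got[s] == pytest.approx(expected[s], rel=1e-10)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(40, (100, 5)).astype(float))
        assert np.exp(np.log(tmm_factors(counts)).mean()) == pytest.approx(1.0)


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        cfg = SimulationConfig(seed=5, n_samples_per_group=5, dispersion=0.0,
                               de_fraction=0.0, tissues=("midgut",))
        recs = [TranscriptRecord(f"t{i}", "ACGT") for i in range(500)]
        counts, samples, _ = simulate_counts(recs, cfg)
        phi = estimate_common_dispersion(counts, samples["condition"])
        assert phi <= 0.05

    def test_recovers_planted_dispersion(self):
        cfg = SimulationConfig(seed=6, n_samples_per_group=5, dispersion=0.2,
                               de_fraction=0.0, tissues=("midgut",))
        recs = [TranscriptRecord(f"t{i}", "ACGT") for i in range(1000)]
        counts, samples, _ = simulate_counts(recs, cfg)
        phi = estimate_common_dispersion(counts, samples["condition"],
                                         tmm_factors(counts))
        assert 0.1 <= phi <= 0.3

    def test_constant_within_groups_is_zero(self):
        counts = pd.DataFrame({"a": [5.0, 9], "b": [5.0, 9],
                               "c": [7.0, 9], "d": [7.0, 9]})
        phi = estimate_common_dispersion(counts, ["u", "u", "f", "f"])
        assert phi == 0.0

    def test_no_replicates_errors(self):
        counts = pd.DataFrame({"a": [5.0], "b": [7.0]})
        with pytest.raises(ValueError, match="replicate"):
            estimate_common_dispersion(counts, ["u", "f"])


class TestExactTest:
    def test_symmetric_split_p_one(self):
        counts = pd.DataFrame([[10.0, 10.0]], index=["t"], columns=["a", "b"])
        res = nb_exact_test(counts, ["unfed", "fed"], dispersion=0.0)
        assert res.loc["t", "pvalue"] == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial(self):
        from scipy.stats import binom

        counts = pd.DataFrame([[10.0, 0.0]], index=["t"], columns=["a", "b"])
        lib = pd.Series({"a": 1e6, "b": 1e6})
        res = nb_exact_test(counts, ["unfed", "fed"], dispersion=0.0,
                            lib_sizes=lib)
        pmf = binom.pmf(np.arange(11), 10, 0.5)
        expected = pmf[pmf <= pmf[10] * (1 + 1e-10)].sum()
        assert res.loc["t", "pvalue"] == pytest.approx(expected)

    def test_label_swap_exchangeability(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(40, (30, 6)).astype(float),
                              columns=[f"s{i}" for i in range(6)])
        labels = ["unfed"] * 3 + ["fed"] * 3
        res_a = nb_exact_test(counts, labels, 0.1)
        res_b = nb_exact_test(counts, labels, 0.1, group1="fed", group2="unfed")
        assert np.allclose(res_a["pvalue"], res_b["pvalue"])
        assert np.allclose(res_a["log2fc"], -res_b["log2fc"])


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.02]) == pytest.approx([0.02])

    def test_hand_evaluated_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
        vec = [0.005, 0.04, 0.02, 0.9, 0.1]
        assert np.allclose(bh_adjust(vec), bh_oracle(vec))

    def test_sorted_fdr_nondecreasing(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        fdr = bh_adjust(p)
        assert np.all(np.diff(fdr[np.argsort(p)]) >= -1e-12)


class TestClassifyDe:
    def test_direction_labels(self):
        de = pd.DataFrame({"log2fc": [2.0, -2.0, 1.0],
                           "pvalue": [0.001, 0.001, 0.9]},
                          index=["a", "b", "c"])
        out = classify_de(de)
        assert out.loc["a", "direction"] == "up_fed"
        assert out.loc["b", "direction"] == "up_unfed"
        assert out.loc["c", "direction"] == "ns"

    def test_planted_de_recovery(self):
        cfg = SimulationConfig(seed=21, n_samples_per_group=6, dispersion=0.15,
                               de_fraction=0.2, de_log2fc=2.0,
                               tissues=("midgut",))
        recs = [TranscriptRecord(f"t{i:04d}", "ACGT") for i in range(600)]
        counts, samples, de_truth = simulate_counts(recs, cfg)
        f = tmm_factors(counts)
        phi = estimate_common_dispersion(counts, samples["condition"], f)
        res = classify_de(nb_exact_test(counts, samples["condition"], phi, f))
        called = res["direction"] != "ns"
        truth = de_truth["is_de"]
        assert (called & truth).sum() / truth.sum() >= 0.8
        assert (called & ~truth).sum() / max(int(called.sum()), 1) <= 0.1
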