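import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evokit.mutbias import (
    MutationRecord,
    calibration_pvalues,
    circular_distances,
    distance_to_nearest_scar,
    essentiality_ratio_test,
    normalized_positions,
    randomization_test,
    summarize_mutations,
    welch_t,
)
from evokit.simulate import GenomeLayout, SimConfig, gen_genome_layout, gen_mutations

# Per-lineage fixed-mutation counts of the nine evolved lineages:
# (all, intergenic, genic indel, genic SNP, N, S)
TABLE1 = {
    "A1": (3, 0, 0, 2, 1, 1),
    "A2": (2, 1, 0, 1, 1, 0),
    "B2": (13, 0, 1, 11, 9, 2),
    "C2": (11, 1, 0, 9, 8, 1),
    "D2": (7, 0, 1, 5, 4, 1),
    "E2": (3, 1, 0, 1, 1, 0),
    "F2": (8, 1, 0, 6, 5, 1),
    "G2": (12, 2, 2, 6, 4, 2),
    "H2": (6, 0, 2, 4, 3, 1),
}


def records_from_counts(counts: dict) -> list[MutationRecord]:
    """Expand per-lineage count rows into individual mutation records."""
    records = []
    pos = 1
    for lin, (all_, inter, indel, snp, n_ns, n_s) in counts.items():
        def add(**kw):
            nonlocal pos
            records.append(MutationRecord(lineage=lin, position=pos, **kw))
            pos += 1000

        for _ in range(n_ns):
            add(mclass="SNP", context="genic", effect="nonsynonymous", gene="g")
        for _ in range(n_s):
            add(mclass="SNP", context="genic", effect="synonymous", gene="g")
        for _ in range(snp - n_ns - n_s):
            add(mclass="SNP", context="genic", gene="g")
        for _ in range(indel):
            add(mclass="indel", context="genic", gene="g")
        for _ in range(inter):
            add(mclass="SNP", context="intergenic")
        for _ in range(all_ - inter - indel - snp):
            add(mclass="structural", context="genic", gene="g")
    return records


class TestMutationRecord:
    def test_effect_only_for_genic_snp(self):
        with pytest.raises(ValueError):
            MutationRecord(lineage="x", position=1, mclass="indel",
                           context="genic", effect="synonymous")
        with pytest.raises(ValueError):
            MutationRecord(lineage="x", position=1, mclass="SNP",
                           context="intergenic", effect="nonsynonymous")

    def test_position_one_based(self):
        with pytest.raises(ValueError):
            MutationRecord(lineage="x", position=0)


class TestSummarize:
    def test_empty(self):
        table = summarize_mutations([], lineages=["A1"])
        assert table.loc["Sum"].sum() == 0

    def test_nine_lineage_totals(self):
        table = summarize_mutations(records_from_counts(TABLE1))
        assert int(table.loc["Sum", "all"]) == 65
        assert int(table.loc["Sum", "intergenic"]) == 6
        assert int(table.loc["Sum", "genic_indel"]) == 6
        assert int(table.loc["Sum", "genic_snp"]) == 45
        assert int(table.loc["Sum", "N"]) == 36
        assert int(table.loc["Sum", "S"]) == 9

    def test_per_lineage_rows_match(self):
        table = summarize_mutations(records_from_counts(TABLE1))
        for lin, row in TABLE1.items():
            got = tuple(int(v) for v in table.loc[lin])
            assert got == row

    def test_n_plus_s_equals_snp_invariant(self):
        # holds here because every genic SNP record carries an effect
        tbl = summarize_mutations(records_from_counts(TABLE1))
        body = tbl.drop(index="Sum")
        assert (body["N"] + body["S"] == body["genic_snp"]).all()

    def test_hand_counted_fixture(self):
        recs = [
            MutationRecord("L", 10, "SNP", "genic", "nonsynonymous", "g1"),
            MutationRecord("L", 20, "SNP", "genic", "nonsynonymous", "g2"),
            MutationRecord("L", 30, "SNP", "genic", "synonymous", "g3"),
            MutationRecord("L", 40, "SNP", "intergenic"),
            MutationRecord("L", 50, "indel", "genic", gene="g4"),
        ]
        t = summarize_mutations(recs)
        assert tuple(int(v) for v in t.loc["L"]) == (5, 1, 1, 3, 2, 1)

    def test_unknown_lineage_rejected(self):
        recs = [MutationRecord("X", 1)]
        with pytest.raises(ValueError):
            summarize_mutations(recs, lineages=["A1"])


class TestDistances:
    def test_on_scar_zero(self, small_layout):
        assert distance_to_nearest_scar(small_layout.scars[0], small_layout) == 0

    def test_wrap_past_origin(self):
        layout = GenomeLayout(length=1000, scars=(100, 900))
        # position 1 (the spec's p=0 in 0-based terms): 99 to scar 100,
        # 101 around the origin to scar 900
        assert distance_to_nearest_scar(1, layout) == 99
        assert distance_to_nearest_scar(1000, layout) == 100

    def test_antipode_half_length(self):
        layout = GenomeLayout(length=1000, scars=(250,))
        assert distance_to_nearest_scar(750, layout) == 500

    def test_linear_flag(self):
        layout = GenomeLayout(length=1000, scars=(900,))
        assert distance_to_nearest_scar(50, layout, circular=False) == 850
        assert distance_to_nearest_scar(50, layout) == 150

    def test_empty_scars_rejected(self):
        layout = GenomeLayout(length=1000, scars=())
        with pytest.raises(ValueError):
            distance_to_nearest_scar(10, layout)

    def test_brute_force_equivalence(self, rng):
        # exhaustive scan over all scars and both arcs on random instances
        for _ in range(1000):
            L = int(rng.integers(10, 10_000))
            n_scars = int(rng.integers(1, 8))
            scars = np.sort(rng.integers(1, L + 1, size=n_scars))
            p = int(rng.integers(1, L + 1))
            brute = min(
                min(abs(p - s), L - abs(p - s)) for s in scars
            )
            fast = circular_distances(p, scars, L)[0]
            assert fast == brute


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed(self):
        # shifted copies: t = -1, Welch-Satterthwaite df = 8, p = 0.3466
        t, df, p = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert df == pytest.approx(8.0)
        assert p == pytest.approx(0.3466, abs=2e-4)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(3, 20)))
            b = rng.normal(loc=0.5, size=int(rng.integers(3, 20)))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_zero_variance(self):
        t, df, p = welch_t([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        t, df, p = welch_t([2, 2, 2], [3, 3, 3])
        assert p == 0.0

    # hundredths keep the shift exactly representable; unconstrained floats
    # let a shift absorb denormal-scale variance and flip degenerate cases
    _vals = st.integers(-1000, 1000).map(lambda i: i / 100.0)

    @given(
        st.lists(_vals, min_size=3, max_size=10),
        st.lists(_vals, min_size=3, max_size=10),
        _vals,
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, a, b, c):
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t([x + c for x in a], [x + c for x in b])
        assert t1 == pytest.approx(t2, abs=1e-8)
        assert p1 == pytest.approx(p2, abs=1e-8)


class TestRandomizationTest:
    def test_replicate_count_and_reproducibility(self, layout):
        obs = gen_mutations(layout, 65, seed=3)
        a = randomization_test(obs, layout, n_replicates=200, seed=9)
        b = randomization_test(obs, layout, n_replicates=200, seed=9)
        assert len(a.p_values) == 200
        np.testing.assert_array_equal(a.p_values, b.p_values)
        assert a.mu_p == b.mu_p

    def test_ci_brackets_mu_p(self, layout):
        obs = gen_mutations(layout, 65, seed=3)
        res = randomization_test(obs, layout, n_replicates=300, seed=9)
        assert res.ci95[0] <= res.mu_p <= res.ci95[1]
        assert np.all((res.p_values >= 0) & (res.p_values <= 1))

    def test_null_observed_not_flagged(self, layout):
        obs = gen_mutations(layout, 65, model="null", seed=77)
        res = randomization_test(obs, layout, n_replicates=500, seed=5)
        assert res.mu_p > 0.05
        assert res.verdict == "no locational bias"

    def test_on_scar_mutations_flagged(self, layout):
        positions = list(layout.scars) + list(layout.scars)[:35]
        res = randomization_test(positions, layout, n_replicates=500, seed=5)
        assert res.mu_p < 0.05
        assert res.verdict == "locational bias"

    def test_rotation_invariance_of_mu_p(self):
        # rotating every coordinate by a constant leaves mu_p unchanged
        L = 500_000
        rng = np.random.default_rng(4)
        scars = tuple(np.sort(rng.integers(1, L + 1, size=6)))
        obs = rng.integers(1, L + 1, size=40)
        shift = 123_456
        rot_scars = tuple(np.sort((np.array(scars) - 1 + shift) % L + 1))
        rot_obs = (obs - 1 + shift) % L + 1
        a = randomization_test(obs, GenomeLayout(length=L, scars=scars),
                               n_replicates=300, seed=8)
        b = randomization_test(rot_obs, GenomeLayout(length=L, scars=rot_scars),
                               n_replicates=300, seed=8)
        # identical seeds draw identical uniforms; distances differ only via
        # the rotated frame, so the p-value distribution matches closely
        assert a.mu_p == pytest.approx(b.mu_p, abs=0.05)

    def test_needs_two_mutations(self, layout):
        with pytest.raises(ValueError):
            randomization_test([layout.scars[0]], layout)

    def test_calibration_uniform(self, layout):
        p = calibration_pvalues(layout, 65, n_pairs=2000, seed=11)
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert 0.03 <= float((p < 0.05).mean()) <= 0.07


class TestEssentialityRatio:
    def test_proportional_null(self):
        res = essentiality_ratio_test(10, 100, 100, 1000)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_study_counts(self):
        res = essentiality_ratio_test(11, 49, 286, 3290)
        assert res.ratio_mut == pytest.approx(22.45, abs=0.01)
        assert res.ratio_all == pytest.approx(8.69, abs=0.01)
        assert 0 < res.p < 0.05
        assert res.p_corrected >= res.p

    def test_degenerate_margin(self):
        res = essentiality_ratio_test(0, 10, 0, 100)
        assert res.p == 1.0
        assert res.warnings

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            essentiality_ratio_test(5, 3, 10, 100)


class TestNormalizedPositions:
    def test_limits(self):
        layout = GenomeLayout(length=1000, scars=(1,))
        f = normalized_positions([1, 500, 1000], layout)
        assert f[0] == pytest.approx(0.0)
        assert f[1] == pytest.approx(0.499, abs=1e-3)
        assert np.all((f >= 0) & (f < 1))

    def test_table_sized_batch(self, layout):
        muts = gen_mutations(layout, 65, seed=6)
        f = normalized_positions(muts, layout)
        assert f.shape == (65,)
        assert np.all((f >= 0) & (f < 1))
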