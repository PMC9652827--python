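"""Weir-Cockerham F_ST, D_XY, permutation tests, GD classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsweep.differentiation import (
    PermutationResult,
    gd_classify,
    permutation_test,
    region_report,
    wc_fst,
    wc_site_components,
    window_dxy,
    window_significance,
)
from strainsweep.synthetic_data import make_structured_fixture
from strainsweep.variants_io import GenotypeMatrix, WindowSpec, make_windows

from ._oracles import wc_fst_anova


def gm_from_dosage(dosage, chrom_len=None, spacing=100):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, s + 1) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        chrom_lengths={"chr1": chrom_len or (s + 1) * spacing},
    )


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = gm_from_dosage([[0]] * 4 + [[2]] * 4)
        assert wc_fst(gm, gm.samples[:4], gm.samples[4:]) == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        block = [[0], [1], [2], [1]]
        gm = gm_from_dosage(block + block)
        assert wc_fst(gm, gm.samples[:4], gm.samples[4:]) <= 0

    def test_hand_computed_site(self):
        # groupA {0/0, 0/1}, groupB {0/1, 1/1}: evaluate WC84 by hand
        gm = gm_from_dosage([[0], [1], [1], [2]])
        a, b, c = wc_site_components(gm, gm.samples[:2], gm.samples[2:])
        # hand evaluation: n=2 per pop, pA=0.25, pB=0.75, hA=hB=0.5
        # nbar=2, nc=2, pbar=0.5, s2=(2*.0625*2)/2=0.125, hbar=0.5
        # a = (2/2)*(0.125 - (0.25 - 0.0625 - 0.125)/1) = 0.0625
        # b = 2*(0.25 - 0.0625 - (3/8)*0.5) = 0
        # c = 0.25
        assert a[0] == pytest.approx(0.0625)
        assert b[0] == pytest.approx(0.0)
        assert c[0] == pytest.approx(0.25)
        est = wc_fst(gm, gm.samples[:2], gm.samples[2:])
        assert est == pytest.approx(0.0625 / 0.3125)

    def test_all_missing_group_errors(self):
        gm = gm_from_dosage([[0], [0], [-1], [-1]])
        with pytest.raises(ValueError):
            wc_fst(gm, gm.samples[:2], gm.samples[2:])

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_anova_oracle(self, data):
        """Property: ratio-of-sums estimate equals literal ANOVA mean squares."""
        n = data.draw(st.integers(4, 10))
        s = data.draw(st.integers(1, 20))
        seed = data.draw(st.integers(0, 2**20))
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(n, s)).astype(np.int8)
        miss = rng.random((n, s)) < 0.1
        dosage[miss] = -1
        nA = data.draw(st.integers(2, n - 2))
        groups = np.array([0] * nA + [1] * (n - nA))
        gm = gm_from_dosage(dosage)
        expected = wc_fst_anova(dosage, groups)
        if not np.isfinite(expected):
            return
        try:
            got = wc_fst(gm, gm.samples[:nA], gm.samples[nA:])
        except ValueError:
            return
        assert got == pytest.approx(expected, abs=1e-12)


class TestDxy:
    def test_identical_monomorphic_zero(self):
        gm = gm_from_dosage(np.zeros((4, 3)), chrom_len=1000)
        out = window_dxy(gm, gm.samples[:2], gm.samples[2:], WindowSpec(1000))
        assert (out["dxy"] == 0).all()

    def test_fixed_difference_closed_form(self):
        gm = gm_from_dosage([[0], [0], [2], [2]], chrom_len=1000)
        out = window_dxy(gm, gm.samples[:2], gm.samples[2:], WindowSpec(1000))
        assert out["dxy"].iloc[0] == pytest.approx(0.001)

    def test_single_site_frequencies_closed_form(self):
        # pA=0.5, pB=0.25 in a 100 bp window -> (0.5*0.75 + 0.5*0.25)/100
        gm = gm_from_dosage([[1], [1], [1], [0]], chrom_len=100, spacing=10)
        out = window_dxy(gm, gm.samples[:2], gm.samples[2:], WindowSpec(100))
        assert out["dxy"].iloc[0] == pytest.approx(0.005)

    def test_window_additivity(self):
        rng = np.random.default_rng(3)
        gm = gm_from_dosage(rng.integers(0, 3, (8, 50)), chrom_len=5100)
        wins = window_dxy(gm, gm.samples[:4], gm.samples[4:], WindowSpec(500))
        total = window_dxy(gm, gm.samples[:4], gm.samples[4:], WindowSpec(5100))
        lhs = (wins["dxy"] * (wins["end"] - wins["start"])).sum()
        rhs = (total["dxy"] * 5100).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_empty_group_rejected(self):
        gm = gm_from_dosage([[0], [0]])
        with pytest.raises(ValueError):
            window_dxy(gm, [], gm.samples, WindowSpec(100))


class TestPermutation:
    def test_result_invariant(self):
        res = PermutationResult(observed=0.5, null_values=np.linspace(0, 0.4, 100))
        assert res.p_empirical == pytest.approx(1 / 101)

    def test_observed_below_all_nulls(self):
        res = PermutationResult(observed=-1.0, null_values=np.linspace(0, 0.4, 100))
        assert res.p_empirical == 1.0

    def test_strong_differentiation_p_below_0_01(self):
        gm, meta = make_structured_fixture(10, 300, 0.4, seed=5)
        res = permutation_test(
            gm, meta.group_samples("popA"), meta.group_samples("popB"), B=100, seed=1
        )
        assert res.p_empirical == pytest.approx(1 / 101)
        assert res.p_empirical < 0.01

    def test_reproducible_and_order_invariant(self):
        gm, meta = make_structured_fixture(8, 200, 0.1, seed=2)
        gA, gB = meta.group_samples("popA"), meta.group_samples("popB")
        r1 = permutation_test(gm, gA, gB, B=50, seed=9)
        r2 = permutation_test(gm, gA, gB, B=50, seed=9)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        # permuting sample storage order must not change the p-value
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm2 = gm.subset_samples([gm.samples[i] for i in perm])
        r3 = permutation_test(gm2, gA, gB, B=50, seed=9)
        assert r3.observed == pytest.approx(r1.observed, abs=1e-12)

    def test_small_pool_warns(self, caplog):
        gm = gm_from_dosage([[0], [1], [2], [1]])
        with caplog.at_level("WARNING"):
            permutation_test(gm, gm.samples[:2], gm.samples[2:], B=100, seed=0)
        assert any("relabelings" in m for m in caplog.messages)


class TestWindowSignificance:
    def test_differentiated_fixture_mostly_significant(self):
        gm, meta = make_structured_fixture(12, 2000, 0.2, seed=13)
        out = window_significance(
            gm,
            meta.group_samples("popA"),
            meta.group_samples("popB"),
            WindowSpec(20_000),
            B_window=199,
            seed=3,
        )
        family = out.dropna(subset=["q_value"])
        assert len(family) >= 9
        frac = (family["q_value"] < 0.05).mean()
        assert frac >= 0.95

    def test_single_window_family_q_equals_p(self):
        gm, meta = make_structured_fixture(
            8, 100, 0.2, seed=1, chrom_lengths={"chr1": 20_000}
        )
        out = window_significance(
            gm,
            meta.group_samples("popA"),
            meta.group_samples("popB"),
            WindowSpec(20_000),
            B_window=19,
            seed=0,
        )
        family = out.dropna(subset=["p_value"])
        assert len(family) == 1
        assert family["q_value"].iloc[0] == family["p_value"].iloc[0]


class TestGD:
    def _stats(self, fst, qv):
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(len(fst)) * 10,
                "end": np.arange(1, len(fst) + 1) * 10,
                "truncated": False,
                "fst": fst,
                "q_value": qv,
            }
        )

    def test_high_significance_flags_gd(self):
        n = 500
        qv = np.full(n, 0.001)
        qv[:2] = 0.9  # 99.6% significant
        rep = gd_classify(self._stats(np.full(n, 0.1), qv))
        assert rep.frac_positive == 1.0
        assert rep.frac_significant == pytest.approx(0.996)
        assert rep.gd_flag

    def test_nonpositive_fst_not_gd(self):
        rep = gd_classify(self._stats(np.full(10, -0.01), np.full(10, 0.5)))
        assert rep.frac_positive == 0.0
        assert not rep.gd_flag

    def test_boundary_is_strict(self):
        qv = np.where(np.arange(100) < 90, 0.01, 0.9)
        rep = gd_classify(self._stats(np.full(100, 0.1), qv))
        assert rep.frac_significant == pytest.approx(0.90)
        assert not rep.gd_flag  # exactly 0.90 does not exceed the threshold


class TestRegionReport:
    def _ws(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 100,
                "end": np.arange(1, n + 1) * 100,
                "fst": values,
            }
        )

    def test_median_region_is_mid_percentile(self):
        ws = self._ws([0.1, 0.2, 0.3, 0.4])
        rep = region_report(ws, "c", 100, 300)  # windows 2 and 3, mean 0.25
        assert rep["percentile"] == pytest.approx(50.0)

    def test_max_window_region_is_percentile_100(self):
        ws = self._ws([0.1, 0.2, 0.3, 0.9])
        rep = region_report(ws, "c", 300, 400)
        assert rep["percentile"] == pytest.approx(100.0)

    def test_region_outside_errors(self):
        ws = self._ws([0.1, 0.2])
        with pytest.raises(ValueError):
            region_report(ws, "c", 10_000, 20_000)
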