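"""F84 distances, neighbor joining, and TPI/COX1 strain assignment."""

import io

import numpy as np
import pandas as pd
import pytest

from strainsweep.strain_id import (
    SaturationError,
    cox1_assign,
    f84_distance,
    f84_distance_matrix,
    f84_distance_se,
    neighbor_joining,
    tpi_assign,
)
from strainsweep.synthetic_data import (
    make_demo_dataset,
    simulate_f84_sequences,
)


class TestF84Distance:
    def test_identical_sequences_zero(self):
        s = "ACGTACGTAC" * 10
        assert f84_distance(s, s) == 0.0

    def test_symmetry(self):
        a = "ACGTACGTACGTGGCA" * 5
        b = "ACCTACGAACGTGGTA" * 5
        assert f84_distance(a, b) == pytest.approx(f84_distance(b, a))

    def test_gap_columns_excluded_pairwise(self):
        a = "ACGT-CGT"
        b = "ACGTACNT"
        # only the 6 mutually unambiguous columns compare; all equal -> 0
        assert f84_distance(a, b) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            f84_distance("ACGT", "ACG")

    def test_saturated_pair_raises(self):
        # complementary strands: every position a transversion
        a = "ACGT" * 25
        b = "TGCA" * 25
        with pytest.raises(SaturationError):
            f84_distance(a, b)

    def test_simulator_consistency_two_taxon(self):
        """Estimated distance within 3 analytic SE of the simulated truth."""
        d_true = 0.10
        seqs = simulate_f84_sequences(
            f"(x:{d_true/2},y:{d_true/2});",
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            ts_tv_ratio=2.0,
            seq_len=100_000,
            seed=5,
        )
        est = f84_distance(seqs["x"], seqs["y"], base_freqs=(0.3, 0.2, 0.2, 0.3))
        se = f84_distance_se(seqs["x"], seqs["y"], base_freqs=(0.3, 0.2, 0.2, 0.3))
        assert abs(est - d_true) <= 3 * se


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        tree = neighbor_joining(d)
        paths = tree.tip_distances()
        # three-point closed form reproduces the input exactly
        for i in "abc":
            for j in "abc":
                assert paths.loc[i, j] == pytest.approx(d.loc[i, j], abs=1e-12)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
            index=list("abcd"),
            columns=list("abcd"),
        )
        tree = neighbor_joining(d)
        paths = tree.tip_distances()
        np.testing.assert_allclose(paths.to_numpy(), d.to_numpy(), atol=1e-9)
        # topology check: a,b neighbors (path a-b shorter than a-c, a-d)
        nwk = tree.to_newick()
        assert ("a" in nwk) and ("d" in nwk)

    @pytest.mark.parametrize("seed", [8, 9, 10])
    def test_matches_reference_implementation_topology(self, seed):
        """Cross-check against the independent scikit-bio NJ on a random
        additive matrix derived from a known 7-taxon tree."""
        import skbio
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        L = rng.uniform(0.1, 1.0, 11).round(3)
        nwk = (
            f"((t0:{L[0]},t1:{L[1]}):{L[2]},(t2:{L[3]},t3:{L[4]}):{L[5]},"
            f"(t4:{L[6]},(t5:{L[7]},t6:{L[8]}):{L[9]}):{L[10]});"
        )
        src = skbio.TreeNode.read(io.StringIO(nwk))
        dm_sk = src.tip_tip_distances()
        names = list(dm_sk.ids)
        d = dm_sk.data
        dm = pd.DataFrame(d, index=names, columns=names)
        mine = neighbor_joining(dm)
        ref = skbio_nj(skbio.DistanceMatrix(d, ids=names))
        mine_sk = skbio.TreeNode.read(io.StringIO(mine.to_newick()))
        mine_sk.unroot()  # NJ trees are unrooted; drop the binary root
        assert mine_sk.compare_rfd(ref) == 0.0
        # additivity: path lengths reproduce the generating matrix
        np.testing.assert_allclose(
            mine.tip_distances().loc[names, names].to_numpy(), d, atol=1e-9
        )

    def test_equal_distances_resolve_deterministically(self):
        d = pd.DataFrame(
            np.ones((4, 4)) - np.eye(4), index=list("abcd"), columns=list("abcd")
        )
        t1 = neighbor_joining(d).to_newick()
        t2 = neighbor_joining(d).to_newick()
        assert t1 == t2

    def test_nan_rejected(self):
        d = pd.DataFrame(
            [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        with pytest.raises(ValueError, match="NaN"):
            neighbor_joining(d)


class TestTpiAssign:
    def test_demo_locus_fully_concordant(self):
        demo = make_demo_dataset(seed=3)
        calls = tpi_assign(demo["gm"], demo["tpi_locus"], demo["tpi_refs"])
        merged = calls.merge(demo["meta"].table, on="sample_id")
        non_hybrid = merged[~merged["is_hybrid"]]
        assert (non_hybrid["tpi_strain"] == non_hybrid["tpi_truth"]).all()

    def test_sample_order_invariance(self):
        demo = make_demo_dataset(seed=3)
        gm = demo["gm"]
        perm = np.random.default_rng(0).permutation(gm.n_samples)
        gm2 = gm.subset_samples([gm.samples[i] for i in perm])
        c1 = tpi_assign(gm, demo["tpi_locus"], demo["tpi_refs"])
        c2 = tpi_assign(gm2, demo["tpi_locus"], demo["tpi_refs"])
        m = c1.merge(c2, on="sample_id", suffixes=("_1", "_2"))
        assert (m["tpi_strain_1"] == m["tpi_strain_2"]).all()

    def test_non_diagnostic_locus_errors(self):
        # identical reference samples always fall in the same PC1 cluster
        import pandas as pd

        from strainsweep.variants_io import GenotypeMatrix

        rng = np.random.default_rng(4)
        dosage = rng.integers(0, 3, (8, 30)).astype(np.int8)
        dosage[1] = dosage[0]
        gm = GenotypeMatrix(
            samples=[f"s{i}" for i in range(8)],
            variants=pd.DataFrame(
                {"chrom": "c", "pos": np.arange(1, 31), "ref": "A", "alt": "G"}
            ),
            dosage=dosage,
        )
        with pytest.raises(ValueError, match="diagnostic"):
            tpi_assign(gm, ("c", 0, 100), {"s0": "C", "s1": "R"})

    def test_too_few_variants_errors(self):
        demo = make_demo_dataset(seed=3)
        with pytest.raises(ValueError, match="polymorphic"):
            tpi_assign(demo["gm"], ("chrZ", 0, 150), demo["tpi_refs"])


class TestCox1Assign:
    def test_query_identical_to_reference(self):
        refs = {"c1": "ACGTACGTAA" * 20, "r1": "ACGTACGTAA"[:5] * 2 + "GGTTCCAAGG" * 19}
        strains = {"c1": "C", "r1": "R"}
        calls, tree = cox1_assign({"q": refs["c1"]}, refs, strains)
        assert calls["cox1_strain"].iloc[0] == "C"
        assert calls["evidence"].iloc[0] > 0

    def test_equidistant_query_ambiguous(self):
        base = "A" * 50 + "C" * 50
        refC = "G" + base[1:]
        refR = base[:-1] + "T"
        query = base  # one substitution from each reference
        calls, _ = cox1_assign(
            {"q": query},
            {"c": refC, "r": refR},
            {"c": "C", "r": "R"},
            base_freqs=(0.25, 0.25, 0.25, 0.25),
        )
        assert calls["cox1_strain"].iloc[0] == "ambiguous"

    def test_two_clade_simulation_fully_concordant(self):
        demo = make_demo_dataset(seed=9)
        calls, tree = cox1_assign(
            demo["cox1_queries"], demo["cox1_refs"], demo["cox1_ref_strains"]
        )
        merged = calls.merge(demo["meta"].table, on="sample_id")
        assert (merged["cox1_strain"] == merged["cox1_truth"]).all()
        # reported NJ tree covers all sequences
        assert set(tree.taxa) == set(demo["cox1_queries"]) | set(demo["cox1_refs"])


def test_concordance_table_reproduces_planted_counts():
    from strainsweep.pipeline import summarize_table1
    from strainsweep.strain_id import combine_calls

    demo = make_demo_dataset(seed=21, n_discordant=3)
    tpi = tpi_assign(demo["gm"], demo["tpi_locus"], demo["tpi_refs"])
    cox1, _ = cox1_assign(
        demo["cox1_queries"], demo["cox1_refs"], demo["cox1_ref_strains"]
    )
    calls = combine_calls(tpi, cox1)
    table = summarize_table1(calls, demo["meta"])
    # corn row: 12 pure popA (TPI C) + 1 hybrid (ambiguous);
    # mitochondria: 3 discordant popA are R, hybrid planted R
    assert table.loc["corn", "tpi_C"] == 12
    assert table.loc["corn", "tpi_ambiguous"] == 1
    assert table.loc["corn", "cox1_R"] == 4
    assert table.loc["corn", "cox1_C"] == 9
    assert table.loc["grass", "tpi_R"] == 12
    assert table.loc["grass", "cox1_R"] == 12
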