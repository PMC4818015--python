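import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_geno
from vocal.core_data import ReferenceMatrix
from vocal.markers import SignificanceSet
from vocal.simbench import (ACTIVATE, REPRESS, EqtlHotspot, GroundTruth, Iqtl,
                            SiblingMap, SimulationConfig, build_gene_groups,
                            evaluate_result, generate_synthetic_reference,
                            partition_cell_types, sample_ground_truth,
                            simulate_expression, simulate_fractions,
                            simulate_genotype_panel)


class TestPartition:
    def test_each_usable_group_contributes_one_pair(self, bench_inputs):
        r, x, sib = partition_cell_types(bench_inputs.ref,
                                         bench_inputs.grouping, seed=0)
        assert len(sib.pairs) == 8
        assert len(r.cell_type_ids) == len(x.cell_type_ids) == 8
        assert not set(r.cell_type_ids) & set(x.cell_type_ids)

    def test_singleton_group_dropped_with_warning(self, small_reference, caplog):
        grouping = {"A": "g1", "B": "g1", "C": "g2"}  # C alone in g2
        with caplog.at_level("WARNING"):
            r, x, sib = partition_cell_types(small_reference, grouping, seed=0)
        assert len(sib.pairs) == 1
        assert "dropped" in caplog.text

    def test_no_usable_group_errors(self, small_reference):
        with pytest.raises(ValueError):
            partition_cell_types(small_reference, {"A": "g1"}, seed=0)


class TestGeneGroups:
    def block_reference(self, n_blocks=3, size=15, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for b in range(n_blocks):
            pattern = rng.normal(size=8)
            for _ in range(size):
                rows.append(2.0 * pattern + rng.normal(0, 0.05, 8))
        genes = [f"b{i // size}_g{i % size}" for i in range(n_blocks * size)]
        return ReferenceMatrix(pd.DataFrame(rows, index=genes,
                                            columns=[f"c{j}" for j in range(8)]))

    def test_three_blocks_recovered_exactly(self):
        r = self.block_reference()
        groups = build_gene_groups(r, list(r.gene_ids))
        assert sorted(len(g) for g in groups) == [15, 15, 15]
        for g in groups:
            assert len({gene.split("_")[0] for gene in g}) == 1

    def test_uncorrelated_pool_errors(self):
        rng = np.random.default_rng(1)
        r = ReferenceMatrix(pd.DataFrame(rng.normal(size=(30, 8)),
                                         index=[f"g{i}" for i in range(30)],
                                         columns=[f"c{j}" for j in range(8)]))
        with pytest.raises(ValueError, match="larger marker pool"):
            build_gene_groups(r, list(r.gene_ids))

    def test_block_of_exactly_ten_is_excluded(self):
        r = self.block_reference(n_blocks=1, size=10)
        with pytest.raises(ValueError):
            build_gene_groups(r, list(r.gene_ids))


class TestGroundTruth:
    def test_counts_and_determinism(self, bench_inputs):
        r, _, _ = partition_cell_types(bench_inputs.ref,
                                       bench_inputs.grouping, seed=0)
        cfg = SimulationConfig(n_iqtl=2, n_eqtl=0, n_strains=30, seed=5)
        a = sample_ground_truth(cfg, bench_inputs.geno, r)
        b = sample_ground_truth(cfg, bench_inputs.geno, r)
        assert len(a.iqtls) == 2 and len(a.hotspots) == 0
        assert len({q.locus for q in a.iqtls}) == 2
        assert len(a.strains) == 30
        assert a.iqtls == b.iqtls and a.strains == b.strains

    def test_round_trip_json(self, tmp_path):
        gt = GroundTruth(iqtls=[Iqtl("v1", "ctA", ACTIVATE)],
                         hotspots=[EqtlHotspot("v2", ("g1", "g2"), REPRESS)],
                         strains=["s1", "s2"], cell_types=["ctA", "ctB"],
                         fractions=pd.DataFrame([[0.5, 0.5], [0.4, 0.6]],
                                                index=["s1", "s2"],
                                                columns=["ctA", "ctB"]))
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.iqtls == gt.iqtls and back.hotspots == gt.hotspots
        pd.testing.assert_frame_equal(back.fractions, gt.fractions)


class TestFractions:
    def gt(self, direction=ACTIVATE):
        return GroundTruth(iqtls=[Iqtl("v0", "ct2", direction)], hotspots=[],
                           strains=["s0", "s1"],
                           cell_types=["ct1", "ct2", "ct3", "ct4"])

    def test_reference_allele_strain_keeps_uniform_fractions(self):
        geno = make_geno([[0], [1]], strains=["s0", "s1"])
        fr = simulate_fractions(self.gt(), geno, gamma_i=0.5)
        np.testing.assert_allclose(fr.loc["s0"], 0.25)

    def test_activating_shift_matches_hand_computation(self):
        geno = make_geno([[0], [1]], strains=["s0", "s1"])
        fr = simulate_fractions(self.gt(), geno, gamma_i=0.5)
        # pre-normalization (0.25, 0.375, 0.25, 0.25) -> /1.125
        np.testing.assert_allclose(
            fr.loc["s1"].round(4), [0.2222, 0.3333, 0.2222, 0.2222])

    def test_repression_shifts_down(self):
        geno = make_geno([[0], [1]], strains=["s0", "s1"])
        fr = simulate_fractions(self.gt(REPRESS), geno, gamma_i=0.5)
        assert fr.loc["s1", "ct2"] < 0.25

    @given(gamma=st.floats(0.0, 0.99), n=st.integers(2, 12),
           carrier=st.booleans())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rows_sum_to_one_and_stay_positive(self, gamma, n, carrier):
        cts = [f"ct{i}" for i in range(n)]
        gt = GroundTruth(iqtls=[Iqtl("v0", cts[0], REPRESS)], hotspots=[],
                         strains=["s0"], cell_types=cts)
        geno = make_geno([[1 if carrier else 0]], strains=["s0"])
        fr = simulate_fractions(gt, geno, gamma_i=gamma)
        assert fr.loc["s0"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (fr.loc["s0"] > 0).all()


class TestExpression:
    def setup_small(self):
        data = pd.DataFrame({"ctA": [1.0, 2.0, 3.0], "ctB": [3.0, 2.0, 1.0]},
                            index=["g0", "g1", "g2"])
        r = ReferenceMatrix(data)
        geno = make_geno([[0], [1]], strains=["s0", "s1"])
        return r, geno

    def test_uniform_noiseless_mixture_is_row_mean(self):
        r, geno = self.setup_small()
        gt = GroundTruth(iqtls=[], hotspots=[], strains=["s0", "s1"],
                         cell_types=["ctA", "ctB"])
        fr = simulate_fractions(gt, geno, gamma_i=0.05)
        cfg = SimulationConfig(n_iqtl=0, n_eqtl=0, sigma2=0.0, seed=0)
        y = simulate_expression(r, fr, gt, geno, cfg)
        np.testing.assert_allclose(y.values,
                                   np.tile(r.data.mean(axis=1).to_numpy()[:, None], 2))

    def test_hotspot_offset_appears_exactly(self):
        r, geno = self.setup_small()
        gt = GroundTruth(iqtls=[],
                         hotspots=[EqtlHotspot("v0", ("g1",), ACTIVATE)],
                         strains=["s0", "s1"], cell_types=["ctA", "ctB"])
        fr = simulate_fractions(gt, geno, gamma_i=0.05)
        cfg = SimulationConfig(n_iqtl=0, n_eqtl=1, gamma_e=0.05, sigma2=0.0, seed=0)
        y = simulate_expression(r, fr, gt, geno, cfg)
        diff = y.data.loc["g1", "s1"] - y.data.loc["g1", "s0"]
        assert diff == pytest.approx(0.05, abs=1e-12)
        assert y.data.loc["g0", "s1"] == pytest.approx(y.data.loc["g0", "s0"])

    def test_noise_variance_matches_sigma2(self):
        rng_free = pd.DataFrame(np.full((100, 100), 2.0),
                                index=[f"g{i}" for i in range(100)],
                                columns=[f"c{j}" for j in range(100)])
        # deterministic part is constant; empirical variance of y ~ sigma2
        r = ReferenceMatrix(rng_free.iloc[:, :2])
        strains = [f"s{i}" for i in range(100)]
        geno = make_geno(np.zeros((100, 1), dtype=int), strains=strains)
        gt = GroundTruth(iqtls=[], hotspots=[], strains=strains,
                         cell_types=["c0", "c1"])
        fr = simulate_fractions(gt, geno, gamma_i=0.05)
        cfg = SimulationConfig(n_iqtl=0, n_eqtl=0, sigma2=1e-4, seed=21)
        y = simulate_expression(r, fr, gt, geno, cfg)
        resid = y.values - 2.0
        assert resid.size == 10_000
        assert np.var(resid) == pytest.approx(1e-4, rel=0.1)


class TestSyntheticReference:
    def test_signature_blocks_tag_their_cell_type(self):
        ref, grouping = generate_synthetic_reference(
            n_groups=4, genes_per_type=10, m=100, separation=4.0,
            signature_overlap=0.1, seed=0)
        from vocal.markers import cell_tagging_scores
        tab = cell_tagging_scores(ref)
        for g in range(4):
            block_genes = [f"g{i:05d}" for i in range(g * 10, (g + 1) * 10)]
            tops = tab.loc[block_genes, "cell_type"]
            assert set(tops) <= {f"ct{g}a", f"ct{g}b"}

    def test_perfect_sibling_correlation_means_identical_profiles(self):
        ref, _ = generate_synthetic_reference(n_groups=2, genes_per_type=5,
                                              m=30, sibling_correlation=1.0,
                                              n_replicates=1, seed=1)
        c = ref.collapse()
        # replicate jitter only; underlying sibling profiles identical
        a = c.data["ct0a"] - c.data["ct0b"]
        assert a.abs().mean() < 0.2

    def test_sibling_correlation_approximately_honored(self):
        ref, _ = generate_synthetic_reference(n_groups=4, genes_per_type=20,
                                              m=500, sibling_correlation=0.9,
                                              seed=3)
        c = ref.collapse().data
        corrs = [np.corrcoef(c["ct%d%s" % (g, "a")], c["ct%d%s" % (g, "b")])[0, 1]
                 for g in range(4)]
        assert np.mean(corrs) == pytest.approx(0.9, abs=0.05)


class TestGenotypePanel:
    def test_markov_panel_shape_and_codes(self):
        g = simulate_genotype_panel(n_strains=10, n_chromosomes=3,
                                    loci_per_chromosome=5, seed=0)
        assert g.codes.shape == (10, 15)
        assert set(np.unique(g.codes.to_numpy())) <= {0, 1}

    def test_low_recombination_gives_long_runs(self):
        g = simulate_genotype_panel(n_strains=50, n_chromosomes=1,
                                    loci_per_chromosome=50,
                                    recomb_prob=0.02, seed=2)
        codes = g.codes.to_numpy()
        flips = (codes[:, 1:] != codes[:, :-1]).mean()
        assert flips == pytest.approx(0.02, abs=0.01)


class TestEvaluate:
    def agg_from(self, scores, cts, loci):
        from vocal.association import AggregatedAssociations
        p = 10.0 ** (-np.asarray(scores, dtype=float))
        return AggregatedAssociations(
            pd.DataFrame(p, index=cts, columns=loci), k=1)

    def simple_truth(self):
        gt = GroundTruth(iqtls=[Iqtl("v0", "gen1", ACTIVATE)], hotspots=[],
                         strains=["s0", "s1"], cell_types=["gen1", "gen2"])
        sib = SiblingMap([("gen1", "dec1"), ("gen2", "dec2")])
        return gt, sib

    def test_perfect_ranking_gives_auc_one(self):
        gt, sib = self.simple_truth()
        agg = self.agg_from([[9, 1], [2, 1]], ["dec1", "dec2"], ["v0", "v1"])
        assert evaluate_result(agg, gt, sib) == 1.0

    def test_all_tied_scores_give_half(self):
        gt, sib = self.simple_truth()
        agg = self.agg_from([[3, 3], [3, 3]], ["dec1", "dec2"], ["v0", "v1"])
        assert evaluate_result(agg, gt, sib) == 0.5

    def test_matches_pairwise_count_oracle(self):
        gt = GroundTruth(iqtls=[Iqtl("v0", "gen1", ACTIVATE),
                                Iqtl("v2", "gen1", ACTIVATE)],
                         hotspots=[], strains=["s0"], cell_types=["gen1"])
        sib = SiblingMap([("gen1", "dec1")])
        scores = [[0.9, 0.8, 0.7, 0.1]]
        agg = self.agg_from(scores, ["dec1"], ["v0", "v1", "v2", "v3"])
        labels = [1, 0, 1, 0]
        flat = np.array(scores[0])
        pos = flat[np.array(labels) == 1]
        neg = flat[np.array(labels) == 0]
        oracle = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert evaluate_result(agg, gt, sib) == pytest.approx(oracle)
        assert oracle == 0.75

    def test_brute_force_agreement_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n_ct, n_loci = int(rng.integers(2, 6)), int(rng.integers(3, 9))
            cts = [f"gen{i}" for i in range(n_ct)]
            sib = SiblingMap([(c, c.replace("gen", "dec")) for c in cts])
            loci = [f"v{j}" for j in range(n_loci)]
            n_pos = int(rng.integers(1, min(n_loci, 3) + 1))
            pos_loci = rng.choice(loci, size=n_pos, replace=False)
            gt = GroundTruth(iqtls=[Iqtl(str(v), cts[0], ACTIVATE)
                                    for v in pos_loci],
                             hotspots=[], strains=["s0"], cell_types=cts)
            scores = rng.integers(0, 5, size=(n_ct, n_loci))  # ties likely
            agg = self.agg_from(scores, [c.replace("gen", "dec") for c in cts],
                                loci)
            positives = {("dec0", str(v)) for v in pos_loci}
            flat = [(scores[i, j], (agg.data.index[i], loci[j]) in positives)
                    for i in range(n_ct) for j in range(n_loci)]
            pos = [s for s, lab in flat if lab]
            neg = [s for s, lab in flat if not lab]
            oracle = np.mean([(p > n) + 0.5 * (p == n)
                              for p in pos for n in neg])
            assert evaluate_result(agg, gt, sib) == pytest.approx(oracle)

    def test_ld_collapse_marks_identical_loci_positive(self):
        gt, sib = self.simple_truth()
        geno = make_geno([[0, 0, 1], [1, 1, 0]], strains=["s0", "s1"])
        agg = self.agg_from([[5, 5, 1], [1, 1, 1]], ["dec1", "dec2"],
                            ["v0", "v1", "v2"])
        plain = evaluate_result(agg, gt, sib)
        collapsed = evaluate_result(agg, gt, sib, ld_collapse=True, geno=geno)
        assert collapsed > plain  # v1 is genotype-identical to the causal v0

    def test_fpr_tpr_mode(self):
        gt, sib = self.simple_truth()
        geno = make_geno([[0, 1], [1, 0]], strains=["s0", "s1"])
        calls = SignificanceSet({("dec1", "v0"), ("dec2", "v1")}, 5.0)
        fpr, tpr = evaluate_result(calls, gt, sib, mode="fpr_tpr", geno=geno)
        assert tpr == 1.0
        assert fpr == pytest.approx(1 / 3)

    def test_unknown_truth_cell_type_errors(self):
        gt, _ = self.simple_truth()
        sib = SiblingMap([("other", "dec1")])
        agg = self.agg_from([[1]], ["dec1"], ["v0"])
        with pytest.raises(ValueError):
            evaluate_result(agg, gt, sib)
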