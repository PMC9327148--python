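import math

import numpy as np
import pytest

from sinescope import splicing, synthetic
from sinescope.io_formats import revcomp


class TestConsensus:
    def test_default_length(self, spec, consensus):
        assert len(consensus) == 231

    def test_repeat_copies_adjacent(self, spec, consensus):
        f = consensus[spec.head_len : spec.head_len + 46]
        r = consensus[spec.head_len + 46 : spec.head_len + 92]
        assert f == r == spec.repeat_unit

    def test_deterministic(self, spec):
        assert synthetic.build_consensus(spec, seed=3) == synthetic.build_consensus(
            spec, seed=3
        )

    def test_motif_once_no_aaaa(self, spec, consensus):
        assert consensus.count(spec.motif) == 1
        assert "AAAA" not in consensus

    def test_invalid_spec_offsets(self):
        with pytest.raises(ValueError):
            synthetic.ConsensusSpec(repeat_unit="A" * 46)

    def test_motif_collision_rejected(self):
        unit = "CCGGTACGCTTCGGCTCCAGGTCACGGAGTTCCCTCGGCATCGTAC"
        with pytest.raises(ValueError, match="collides"):
            synthetic.ConsensusSpec(repeat_unit=unit)


class TestBackground:
    def test_gc_within_binomial_ci(self):
        g = synthetic.generate_background(10_000, 0.4, seed=1)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / 10_000
        se = math.sqrt(0.4 * 0.6 / 10_000)
        assert abs(gc - 0.4) < 3 * se

    def test_single_base(self):
        g = synthetic.generate_background(1, 0.5, seed=2)
        assert len(g.sequence) == 1 and g.sequence in "ACGT"

    def test_seed_sensitivity(self):
        a = synthetic.generate_background(500, 0.5, seed=1)
        b = synthetic.generate_background(500, 0.5, seed=2)
        assert a.sequence != b.sequence

    def test_bad_args(self):
        with pytest.raises(ValueError):
            synthetic.generate_background(0, 0.5)
        with pytest.raises(ValueError):
            synthetic.generate_background(10, 1.0)


class TestImplants:
    def test_class_i_when_unspliced(self, consensus):
        bg = synthetic.generate_background(50_000, 0.4, seed=3)
        _, truth = synthetic.implant_elements(bg, consensus, 5, sub_rate=0.0, seed=4)
        assert all(t.headbody.length == 231 and t.class_label == "I" for t in truth)

    def test_class_ii_when_spliced(self, consensus, dual_sites):
        bg = synthetic.generate_background(50_000, 0.4, seed=5)
        _, truth = synthetic.implant_elements(
            bg, consensus, 5, spliced_prob=1.0, splice_sites=dual_sites, seed=6
        )
        assert all(t.headbody.length == 185 and t.class_label == "II" for t in truth)

    def test_truth_byte_exact_at_zero_sub_rate(self, consensus):
        bg = synthetic.generate_background(60_000, 0.4, seed=7)
        genome, truth = synthetic.implant_elements(bg, consensus, 6, sub_rate=0.0, seed=8)
        for t in truth:
            s = genome.sequence
            assert s[t.tsd_left.start : t.tsd_left.end] == t.tsd_seq
            assert s[t.tsd_right.start : t.tsd_right.end] == t.tsd_seq
            assert s[t.headbody.start : t.headbody.end] == consensus
            tail = s[t.tail.start : t.tail.end]
            assert tail.count("A") / len(tail) >= 0.6

    def test_tail_a_rich(self, implant_genome):
        genome, truth = implant_genome
        for t in truth:
            tail = genome.sequence[t.tail.start : t.tail.end]
            assert tail.count("A") / len(tail) >= 0.6

    def test_tsd_lengths_in_range(self, implant_genome):
        _, truth = implant_genome
        assert all(8 <= len(t.tsd_seq) <= 20 for t in truth)
        assert all("AAAA" not in t.tsd_seq for t in truth)

    def test_tandem_single_outer_pair(self, consensus):
        bg = synthetic.generate_background(30_000, 0.4, seed=9)
        genome, truth = synthetic.implant_elements(
            bg, consensus, 2, tandem_prob=1.0, seed=10
        )
        assert len(truth) == 2
        assert truth[0].tandem_group == truth[1].tandem_group == 0
        assert truth[0].tsd_left == truth[1].tsd_left
        assert truth[0].tsd_right == truth[1].tsd_right
        s = genome.sequence
        assert s[truth[0].tsd_left.start : truth[0].tsd_left.end] == truth[0].tsd_seq

    def test_nested_inside_host(self, consensus):
        bg = synthetic.generate_background(30_000, 0.4, seed=11)
        _, truth = synthetic.implant_elements(bg, consensus, 2, nested_prob=1.0, seed=12)
        host = next(t for t in truth if t.nested_parent is None)
        inner = next(t for t in truth if t.nested_parent is not None)
        assert inner.nested_parent == host.element_id
        assert host.span.strictly_contains(inner.span)

    def test_revcomp_implant(self, consensus):
        bg = synthetic.generate_background(30_000, 0.4, seed=13)
        genome, truth = synthetic.implant_elements(
            bg, consensus, 2, sub_rate=0.0, revcomp_prob=1.0, seed=14
        )
        t = truth[0]
        assert t.strand == "-"
        assert revcomp(genome.sequence[t.headbody.start : t.headbody.end]) == consensus

    def test_spliced_matches_excision(self, consensus, dual_sites, spec):
        """Cross-module consistency: class II implants are class I minus the
        inter-site segment produced by excise_by_splice."""
        bg = synthetic.generate_background(30_000, 0.4, seed=15)
        genome, truth = synthetic.implant_elements(
            bg, consensus, 3, sub_rate=0.0, spliced_prob=1.0,
            splice_sites=dual_sites, seed=16,
        )
        expected = splicing.excise_by_splice(consensus, *dual_sites)
        for t in truth:
            assert genome.sequence[t.headbody.start : t.headbody.end] == expected

    def test_determinism(self, consensus):
        bg = synthetic.generate_background(40_000, 0.4, seed=17)
        g1, t1 = synthetic.implant_elements(bg, consensus, 4, sub_rate=0.02, seed=18)
        g2, t2 = synthetic.implant_elements(bg, consensus, 4, sub_rate=0.02, seed=18)
        assert g1.sequence == g2.sequence and t1 == t2

    def test_inverted_range_errors(self, consensus):
        bg = synthetic.generate_background(30_000, 0.4, seed=19)
        with pytest.raises(ValueError, match="range"):
            synthetic.implant_elements(bg, consensus, 2, tsd_len_range=(20, 8))

    def test_too_small_background(self, consensus):
        bg = synthetic.generate_background(1000, 0.4, seed=20)
        with pytest.raises(ValueError):
            synthetic.implant_elements(bg, consensus, 10)


class TestAnnotation:
    def test_no_exonization_when_prob_zero(self, implant_genome, spec):
        genome, truth = implant_genome
        genes = synthetic.synthesize_annotation(
            genome, truth, 6, exon_in_element_prob=0.0, seed=21, consensus_spec=spec
        )
        for g in genes:
            for exon in g.features.get("exon", []):
                for t in truth:
                    assert not (
                        t.span.start < exon.start < t.span.end
                        or t.span.start < exon.end < t.span.end
                    )

    def test_exonized_boundaries_canonical(self, annotated):
        genome, truth, genes = annotated
        seq = genome.sequence
        n_inside = 0
        for g in genes:
            for exon in g.features.get("exon", []):
                for t in truth:
                    if t.span.start < exon.end < t.span.end:
                        n_inside += 1
                        assert seq[exon.end : exon.end + 2] == "GT"
                    if t.span.start < exon.start < t.span.end:
                        n_inside += 1
                        assert seq[exon.start - 2 : exon.start] == "AG"
        assert n_inside > 0

    def test_has_rna_genes_and_utrs(self, annotated):
        _, _, genes = annotated
        assert any("rna_gene" in g.features for g in genes)
        assert any("five_prime_utr" in g.features for g in genes)

    def test_too_small_genome_errors(self, spec, consensus):
        bg = synthetic.generate_background(5_000, 0.4, seed=22)
        genome, truth = synthetic.implant_elements(bg, consensus, 1, seed=23)
        with pytest.raises((ValueError, RuntimeError)):
            synthetic.synthesize_annotation(
                genome, truth, 50, seed=24, consensus_spec=spec
            )


@pytest.fixture(scope="module")
def sim(implant_genome):
    genome, truth = implant_genome
    return synthetic.simulate_methylomes(
        genome,
        truth,
        dm_elements=[truth[0].element_id, truth[1].element_id],
        delta=0.4,
        depth_range=(30, 60),
        overdispersion=0.01,
        seed=25,
    )


@pytest.fixture(scope="module")
def expr_setup(implant_genome):
    genome, truth = implant_genome
    msim = synthetic.simulate_methylomes(
        genome,
        truth,
        dm_elements=[t.element_id for t in truth[:4]],
        delta=0.4,
        seed=30,
    )
    e2g = {t.element_id: f"g{i:03d}" for i, t in enumerate(truth[:4])}
    from sinescope.io_formats import GeneModel, Interval

    genes = []
    for i in range(4):
        iv = Interval(genome.name, 10 + i * 100, 60 + i * 100, "+")
        genes.append(GeneModel(f"g{i:03d}", genome.name, "+", iv.start, {"gene": [iv]}))
    return genome, truth, msim, e2g, genes


class TestMethylomes:
    def test_paired_design(self, sim):
        assert len(sim.design) == 16
        tissues = {t for _, _, t in sim.design}
        assert tissues == {"muscle", "testis"}

    def test_depths_in_range(self, sim):
        for recs in sim.records.values():
            assert all(30 <= r.n_total <= 60 for r in recs)

    def test_dm_truth_signed(self, sim):
        assert all(v == -0.4 for v in sim.dm_truth.values())

    def test_delta_zero_no_tissue_difference(self, implant_genome):
        genome, truth = implant_genome
        sim = synthetic.simulate_methylomes(
            genome, truth, dm_fraction=0.0, delta=0.0, seed=26
        )
        assert sim.dm_truth == {}
        for (eid, sid), m in sim.element_true_means.items():
            ind = sid.split("_")[1]
            other = ("testis_" + ind) if sid.startswith("muscle") else ("muscle_" + ind)
            assert m == pytest.approx(sim.element_true_means[(eid, other)])

    def test_law_of_large_numbers(self, implant_genome):
        """delta=0.4, vanishing overdispersion, huge depth: element tissue
        means differ by ~0.4 on the probability scale."""
        genome, truth = implant_genome
        sim = synthetic.simulate_methylomes(
            genome,
            truth,
            dm_elements=[truth[0].element_id],
            delta=0.4,
            depth_range=(10_000, 10_000),
            overdispersion=0.0,
            indiv_sd=0.0,
            n_background_cpgs=0,
            seed=27,
        )
        eid = truth[0].element_id
        span = truth[0].span
        diffs = []
        for i in range(1, 9):
            levels = {}
            for tis in ("muscle", "testis"):
                recs = [
                    r
                    for r in sim.records[f"{tis}_{i}"]
                    if span.start <= r.pos < span.end
                ]
                levels[tis] = np.mean([r.n_meth / r.n_total for r in recs])
            diffs.append(levels["muscle"] - levels["testis"])
        assert np.mean(diffs) == pytest.approx(0.4, abs=0.02)

    def test_deterministic(self, implant_genome):
        genome, truth = implant_genome
        a = synthetic.simulate_methylomes(genome, truth, dm_fraction=0.0, seed=28)
        b = synthetic.simulate_methylomes(genome, truth, dm_fraction=0.0, seed=28)
        assert a.records == b.records

    def test_delta_too_large(self, implant_genome):
        genome, truth = implant_genome
        with pytest.raises(ValueError):
            synthetic.simulate_methylomes(genome, truth, background_mean=0.3, delta=0.4)


class TestExpression:
    def test_sign_plus_monotone(self, expr_setup):
        genome, truth, sim, e2g, genes = expr_setup
        eid = truth[0].element_id
        expr = synthetic.simulate_expression(
            genes, sim, {eid: "+"}, beta=4.0, noise_sd=0.0, seed=31, element_to_gene=e2g
        )
        import scipy.stats as sps

        meths = [sim.element_true_means[(eid, s)] for s, _, _ in sim.design]
        vals = [expr.loc[e2g[eid], s] for s, _, _ in sim.design]
        rho = sps.spearmanr(meths, vals).statistic
        assert rho == pytest.approx(1.0)

    def test_sign_minus_monotone(self, expr_setup):
        genome, truth, sim, e2g, genes = expr_setup
        eid = truth[1].element_id
        expr = synthetic.simulate_expression(
            genes, sim, {eid: "-"}, beta=4.0, noise_sd=0.0, seed=32, element_to_gene=e2g
        )
        import scipy.stats as sps

        meths = [sim.element_true_means[(eid, s)] for s, _, _ in sim.design]
        vals = [expr.loc[e2g[eid], s] for s, _, _ in sim.design]
        assert sps.spearmanr(meths, vals).statistic == pytest.approx(-1.0)

    def test_beta_zero_independent(self, expr_setup):
        genome, truth, sim, e2g, genes = expr_setup
        eid = truth[2].element_id
        expr = synthetic.simulate_expression(
            genes, sim, {eid: "+"}, beta=0.0, noise_sd=0.5, seed=33, element_to_gene=e2g
        )
        import scipy.stats as sps

        meths = [sim.element_true_means[(eid, s)] for s, _, _ in sim.design]
        vals = [expr.loc[e2g[eid], s] for s, _, _ in sim.design]
        assert abs(sps.spearmanr(meths, vals).statistic) < 0.9
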