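import numpy as np
import pytest
from scipy.stats import binom, chisquare

from sinescope import calibration, splicing, synthetic
from sinescope.calibration import CalibratedElement
from sinescope.io_formats import GeneModel, GenomeSequence, Interval
from sinescope.splicing import (
    NullThreshold,
    SpliceSignal,
    excise_by_splice,
    find_dual_sites,
    hot_sites,
    mark_splice_signals,
    null_counts,
    null_threshold,
    project_to_consensus,
    select_cds_partial_overlaps,
    signal_profile,
)


def _element(chrom, start, end, strand="+", eid="e1"):
    span = Interval(chrom, start, end, strand)
    return CalibratedElement(
        full_span=span,
        strand=strand,
        tsd=None,
        headbody_span=span,
        tail_span=None,
        class_label="I",
        boundary_method="tsd",
        element_id=eid,
    )


def _gene(gid, chrom, strand, exons, cds=None, utr3=None, rna=False):
    feats = {"exon": [Interval(chrom, s, e, strand) for s, e in exons]}
    span = Interval(chrom, min(s for s, _ in exons), max(e for _, e in exons), strand)
    feats["gene"] = [span]
    if cds:
        feats["CDS"] = [Interval(chrom, s, e, strand) for s, e in cds]
    if utr3:
        feats["three_prime_utr"] = [Interval(chrom, s, e, strand) for s, e in utr3]
    if rna:
        feats = {"rna_gene": [span], "gene": [span]}
    tss = span.start if strand == "+" else span.end - 1
    return GeneModel(gid, chrom, strand, tss, feats)


class TestSelection:
    def test_intronic_element_excluded(self):
        el = _element("c", 500, 700)
        g = _gene("g1", "c", "+", [(100, 200), (800, 900)], cds=[(100, 900)])
        assert select_cds_partial_overlaps([el], [g]) == []

    def test_partial_overlap_with_cds_included(self):
        el = _element("c", 500, 700)
        g = _gene("g1", "c", "+", [(100, 550), (800, 900)], cds=[(100, 550)])
        assert select_cds_partial_overlaps([el], [g]) == [el]

    def test_utr_overlap_excluded(self):
        el = _element("c", 500, 700)
        g = _gene(
            "g1", "c", "+", [(100, 550), (800, 900)],
            cds=[(100, 550)], utr3=[(520, 560)],
        )
        assert select_cds_partial_overlaps([el], [g]) == []

    def test_rna_gene_overlap_excluded(self):
        el = _element("c", 500, 700)
        g = _gene("g1", "c", "+", [(100, 550), (800, 900)], cds=[(100, 550)])
        rna = _gene("r1", "c", "+", [(600, 650)], rna=True)
        assert select_cds_partial_overlaps([el], [g, rna]) == []


class TestMarking:
    def test_donor_inside_element(self):
        seq = "C" * 550 + "GT" + "C" * 448
        genome = GenomeSequence("c", seq)
        el = _element("c", 500, 700)
        g = _gene("g1", "c", "+", [(100, 550), (800, 900)])
        sigs = mark_splice_signals(el, [g], genome)
        donors = [s for s in sigs if s.kind == "5"]
        assert len(donors) == 1
        assert donors[0].element_offset == 50

    def test_acceptor_on_minus_is_T(self):
        # - strand gene: acceptor intron is genomically right of exon end (CT)
        seq = "C" * 600 + "CT" + "C" * 398
        genome = GenomeSequence("c", seq)
        el = _element("c", 500, 700, strand="+")
        g = _gene("g1", "c", "-", [(550, 600), (300, 400)])
        sigs = mark_splice_signals(el, [g], genome)
        assert any(s.kind == "T" for s in sigs)

    def test_non_canonical_excluded_from_profile(self):
        seq = "C" * 550 + "AT" + "C" * 448
        genome = GenomeSequence("c", seq)
        el = _element("c", 500, 700)
        g = _gene("g1", "c", "+", [(100, 550), (800, 900)])
        sigs = mark_splice_signals(el, [g], genome)
        assert sigs[0].kind == "5nc"
        prof = signal_profile(
            [s.__class__(**{**s.__dict__, "consensus_pos": 10}) for s in sigs],
            (1, 93),
        )
        assert prof.n_signals == 0


class TestProjection:
    def test_identity_alignment(self, consensus):
        sig = SpliceSignal("e", 124, "5", "t")
        out = project_to_consensus(sig, consensus, consensus)
        assert out.consensus_pos == 125

    def test_deletion_shifts_projection(self, consensus):
        # remove 3 nt well 5' of the signal
        mutated = consensus[:50] + consensus[53:]
        sig = SpliceSignal("e", 121, "5", "t")  # offset in the deleted coords
        out = project_to_consensus(sig, mutated, consensus)
        assert out.consensus_pos == 125

    def test_insertion_maps_to_next_column(self, consensus):
        from sinescope.aligndist import global_align

        mutated = consensus[:100] + "TTTGGTCA" + consensus[100:]
        sig = SpliceSignal("e", 103, "5", "t")  # inside the inserted block
        out = project_to_consensus(sig, mutated, consensus)
        # verify the stated rule against the actual alignment: the signal
        # column is a consensus gap, and the projection is the next non-gap
        # consensus column 3' of it
        res = global_align(mutated, consensus)
        e_off, c_pos = -1, 0
        expected = None
        hit_gap = False
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if cb != "-":
                c_pos += 1
            if ca != "-":
                e_off += 1
                if e_off == 103:
                    hit_gap = cb == "-"
                    expected = c_pos if cb != "-" else c_pos + 1
        assert hit_gap  # the signal offset really falls in an insertion
        assert out.consensus_pos == expected

    def test_diverged_element_dropped(self, consensus):
        junk = "AT" * 120
        sig = SpliceSignal("e", 10, "5", "t")
        assert project_to_consensus(sig, junk, consensus) is None


class TestProfile:
    def test_counts(self):
        sigs = [SpliceSignal("e", 0, "5", "t", consensus_pos=42) for _ in range(7)]
        prof = signal_profile(sigs, (1, 93))
        assert prof.counts == {42: 7} and prof.n_signals == 7

    def test_empty(self):
        assert signal_profile([], (1, 93)).n_signals == 0

    def test_window_edges(self):
        sigs = [
            SpliceSignal("e", 0, "5", "t", consensus_pos=p) for p in (1, 93, 94)
        ]
        prof = signal_profile(sigs, (1, 93))
        assert prof.n_signals == 2 and 94 not in prof.counts


class TestNullThreshold:
    def test_default_parameters_give_six(self):
        thr = null_threshold(93, 188, 10_000, 0.01, seed=1)
        assert thr.k == 6
        assert thr.tail_prob_at_k <= 0.01

    def test_exact_binomial_tiny_case(self):
        # Binomial(2, 1/2): P(>0)=0.75, P(>1)=0.25 -> k=1 at alpha 0.5
        thr = null_threshold(2, 2, alpha=0.5, method="exact")
        assert thr.k == 1
        assert thr.tail_prob_at_k == pytest.approx(0.25)

    def test_empirical_matches_binomial_tail(self):
        counts = null_counts(93, 188, 10_000, seed=2)
        emp = np.count_nonzero(counts > 6) / counts.size
        expected = binom(188, 1 / 93).sf(6)
        se = np.sqrt(expected * (1 - expected) / counts.size)
        assert abs(emp - expected) <= 3 * se

    def test_pooled_distribution_binomial_gof(self):
        counts = null_counts(93, 188, 10_000, seed=3)
        dist = binom(188, 1 / 93)
        edges = list(range(0, 9))
        obs = np.array(
            [np.count_nonzero(counts == k) for k in edges] + [np.count_nonzero(counts > 8)],
            dtype=float,
        )
        exp = np.array([dist.pmf(k) for k in edges] + [dist.sf(8)]) * counts.size
        stat, p = chisquare(obs, exp)
        assert p > 0.001

    def test_bad_args(self):
        with pytest.raises(ValueError):
            null_threshold(0, 10)


class TestHotSites:
    THR = NullThreshold(93, 15, 0, 0.01, k=6, tail_prob_at_k=0.005)

    def _profile(self):
        sigs = []
        for pos, n in ((10, 7), (20, 6), (30, 2)):
            sigs += [SpliceSignal("e", 0, "5", "t", consensus_pos=pos)] * n
        return signal_profile(sigs, (1, 93))

    def test_strict_rule(self):
        assert hot_sites(self._profile(), self.THR) == [10]

    def test_inclusive_rule(self):
        assert hot_sites(self._profile(), self.THR, inclusive=True) == [10, 20]

    def test_empty(self):
        assert hot_sites(signal_profile([], (1, 93)), self.THR) == []


class TestDualSites:
    def test_offset_difference_is_unit_length(self, spec):
        (donor, acceptor), = find_dual_sites(spec)
        assert acceptor - donor == 46

    def test_three_repeats_two_pairings(self):
        spec3 = synthetic.ConsensusSpec(n_repeats=3)
        pairs = find_dual_sites(spec3)
        assert len(pairs) == 2
        assert all(a - d == 46 for d, a in pairs)

    def test_missing_site_errors(self):
        class FakeSpec:
            repeat_unit = "C" * 46
            donor_offset = 20
            acceptor_offset = 20
            head_len = 104
            repeat_len = 46
            n_repeats = 2

        with pytest.raises(ValueError):
            find_dual_sites(FakeSpec())


class TestExcision:
    def test_class_i_to_class_ii(self, consensus, dual_sites):
        product = excise_by_splice(consensus, *dual_sites)
        assert len(product) == 185

    def test_product_is_f_r_chimera(self, spec, dual_sites):
        """Tag the bases of each repeat copy, then check the retained repeat
        is F's prefix joined to R's suffix."""
        donor, acceptor = dual_sites
        head = "H" * spec.head_len
        f = list(spec.repeat_unit)
        r = list(spec.repeat_unit)
        trailer = "Z" * spec.trailer_len
        # build a positional map alongside the real sequence
        tags = head + "".join("F" for _ in f) + "".join("R" for _ in r) + trailer
        real = synthetic.build_consensus(spec, seed=0)
        product_tags = tags[:donor] + tags[acceptor:]
        product = excise_by_splice(real, donor, acceptor)
        assert len(product) == len(product_tags)
        kept_f = product_tags.count("F")
        kept_r = product_tags.count("R")
        assert kept_f == spec.donor_offset
        assert kept_f + kept_r == 46
        # the retained repeat equals F-prefix + R-suffix (== the unit, F == R)
        start = spec.head_len
        assert product[start : start + 46] == spec.repeat_unit

    def test_flanks_conserved(self, consensus, dual_sites):
        donor, acceptor = dual_sites
        product = excise_by_splice(consensus, donor, acceptor)
        assert product[:donor] == consensus[:donor]
        assert product[donor:] == consensus[acceptor:]

    def test_branch_site_check(self, consensus, dual_sites):
        product = excise_by_splice(consensus, *dual_sites, check_branch=True)
        assert len(product) == 185
        with pytest.raises(ValueError, match="branch"):
            excise_by_splice("C" * 50 + "GT" + "C" * 100 + "AG" + "C" * 50, 50, 154,
                             check_branch=True)

    def test_non_canonical_errors(self):
        with pytest.raises(ValueError, match="GT"):
            excise_by_splice("GACCCCAG", 0, 8)
        with pytest.raises(ValueError):
            excise_by_splice("GTCCCCAG", 6, 2)

    def test_tandem_transcript_bookkeeping(self, consensus, spec, dual_sites):
        """Excision between element 1's donor and element 2's acceptor on a
        tandem two-element transcript: exact length accounting."""
        donor, acceptor = dual_sites
        transcript = consensus + consensus
        acceptor2 = acceptor + len(consensus)
        product = excise_by_splice(transcript, donor, acceptor2)
        assert len(product) == 2 * len(consensus) - (acceptor2 - donor)
        assert product == consensus[:donor] + consensus[acceptor:]


class TestEndToEnd:
    def test_hot_sites_at_dual_offsets(self, spec, annotated, consensus):
        genome, truth, genes = annotated
        hits = calibration.scan_hits(genome, consensus)
        elements, _ = calibration.calibrate_all(genome, hits)
        selected = select_cds_partial_overlaps(elements, genes)
        assert selected
        signals = []
        for el in selected:
            s = genome.sequence[el.headbody_span.start : el.headbody_span.end]
            for sig in mark_splice_signals(el, genes, genome):
                proj = project_to_consensus(sig, s, consensus)
                if proj is not None:
                    signals.append(proj)
        window = (spec.head_len + 1, spec.head_len + 93)
        profile = signal_profile(signals, window)
        thr = null_threshold(93, max(profile.n_signals, 1), 10_000, 0.01, seed=4)
        hot = hot_sites(profile, thr)
        donor_pos = spec.head_len + spec.donor_offset + 1
        acceptor_ag_pos = spec.head_len + spec.repeat_len + spec.acceptor_offset - 1
        assert set(hot) <= {donor_pos, acceptor_ag_pos}
        assert hot  # at least one dual-function site is hot
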