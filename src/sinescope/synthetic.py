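"""Synthetic genomes, annotations, methylomes and expression with ground truth.

Everything here is a pure function of its inputs and a seed, so any
downstream stage can be tested against exact truth tables without
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from sinescope.io_formats import GenomeSequence, GeneModel, Interval, MethylationRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: hand-designed 46-nt direct-repeat unit: AG|GT dual splice site at
#: offset 20, CTGAT branch-site motif at offset 30, CpG-rich, no AAAA run
DEFAULT_REPEAT_UNIT = "CCGGTACGCTTCGGCTCCAGGTCACGTTCGCTGATCGGCATCGTAC"

A_BOX = "TGGCTCAGTGG"
B_BOX = "GGTTCGAATCC"


@dataclass(frozen=True)
class ConsensusSpec:
    """Layout of the head–body consensus: promoter head, tandem direct
    repeats (F = R by construction), and a 3' linker carrying the
    conserved motif. Default assembled length is 231 nt."""

    head_len: int = 104
    repeat_unit: str = DEFAULT_REPEAT_UNIT
    n_repeats: int = 2
    a_box_pos: int = 8
    b_box_pos: int = 70
    trailer_len: int = 35
    motif: str = "GGAGTTCCC"
    motif_offset: int = 20  # within the trailer
    donor_offset: int = 20  # GT start within each repeat unit
    acceptor_offset: int = 20  # AG end within each repeat unit

    def __post_init__(self) -> None:
        u = self.repeat_unit
        if self.donor_offset + 2 > len(u) or self.acceptor_offset < 2:
            raise ValueError("splice offsets outside the repeat unit")
        if u[self.donor_offset : self.donor_offset + 2] != "GT":
            raise ValueError("repeat unit lacks GT at donor_offset")
        if u[self.acceptor_offset - 2 : self.acceptor_offset] != "AG":
            raise ValueError("repeat unit lacks AG before acceptor_offset")
        if self.motif in u:
            raise ValueError("conserved motif collides with the repeat unit")
        if self.motif_offset + len(self.motif) > self.trailer_len:
            raise ValueError("motif does not fit in the trailer")
        if self.a_box_pos + len(A_BOX) > self.b_box_pos or self.b_box_pos + len(B_BOX) > self.head_len:
            raise ValueError("promoter boxes do not fit in the head")

    @property
    def repeat_len(self) -> int:
        return len(self.repeat_unit)

    @property
    def total_len(self) -> int:
        return self.head_len + self.n_repeats * self.repeat_len + self.trailer_len


@dataclass
class ImplantTruth:
    """Exact ground truth for one implanted element (final coordinates)."""

    element_id: str
    span: Interval  # between the two TSD copies
    tsd_seq: str
    tsd_left: Interval
    tsd_right: Interval
    headbody: Interval
    tail: Interval
    class_label: str  # "I" or "II"
    strand: str = "+"
    tandem_group: int | None = None
    nested_parent: str | None = None
    spliced: bool = False
    n_subs: int = 0


def _random_filler(rng: np.random.Generator, n: int, p=(0.2, 0.3, 0.3, 0.2)) -> str:
    """Random DNA with no AAAA run (A suppressed after three A's)."""
    out: list[str] = []
    run = 0
    bases = "ACGT"
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    draws = rng.choice(4, size=4 * n + 16, p=p)
    k = 0
    while len(out) < n:
        b = bases[draws[k]]
        k += 1
        if b == "A":
            if run >= 3:
                continue
            run += 1
        else:
            run = 0
        out.append(b)
    return "".join(out)


def build_consensus(spec: ConsensusSpec = ConsensusSpec(), seed: int = 0) -> str:
    """Assemble the head–body consensus deterministically for (spec, seed).

    The result contains the A-box/B-box head, ``n_repeats`` identical
    copies of the repeat unit, exactly one occurrence of the conserved
    motif in the trailer, and no AAAA run anywhere (the tail splitter's
    signal is reserved for real tails).
    """
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        head = list(_random_filler(rng, spec.head_len))
        head[spec.a_box_pos : spec.a_box_pos + len(A_BOX)] = A_BOX
        head[spec.b_box_pos : spec.b_box_pos + len(B_BOX)] = B_BOX
        trailer = list(_random_filler(rng, spec.trailer_len))
        trailer[spec.motif_offset : spec.motif_offset + len(spec.motif)] = spec.motif
        seq = "".join(head) + spec.repeat_unit * spec.n_repeats + "".join(trailer)
        if "AAAA" in seq or seq.endswith("A"):
            # a trailing A would blur the head-body/tail boundary
            continue
        if seq.count(spec.motif) != 1:
            continue
        assert len(seq) == spec.total_len
        return seq
    raise RuntimeError("could not assemble a consensus satisfying the constraints")


def generate_background(length: int, gc_fraction: float, seed: int = 0) -> GenomeSequence:
    """I.i.d. background sequence with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _BASES[idx].tobytes().decode()
    return GenomeSequence("chrS", seq)


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float) -> tuple[str, int]:
    if sub_rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(hits)


def _random_tsd(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    at = (1 - gc) / 2
    for _ in range(100):
        idx = rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at])
        s = _BASES[idx].tobytes().decode()
        if "AAAA" not in s:
            return s
    raise RuntimeError("could not draw a TSD without an AAAA run")


def _poly_a_tail(rng: np.random.Generator, length: int, contamination: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < contamination:
            out.append("CGT"[rng.integers(3)])
        else:
            out.append("A")
    return "".join(out)


@dataclass
class _Insert:
    pos: int  # position in the background coordinate system
    seq: str
    truths: list[ImplantTruth]  # spans relative to the insert start


def _single_unit(
    rng: np.random.Generator,
    consensus: str,
    element_id: str,
    tsd_len_range,
    tail_len_range,
    sub_rate,
    spliced_prob,
    splice_sites,
    tail_contamination,
    revcomp_prob,
) -> tuple[str, list[ImplantTruth]]:
    tsd = _random_tsd(rng, int(rng.integers(tsd_len_range[0], tsd_len_range[1] + 1)))
    tail = _poly_a_tail(
        rng, int(rng.integers(tail_len_range[0], tail_len_range[1] + 1)), tail_contamination
    )
    spliced = bool(rng.random() < spliced_prob)
    body = consensus
    if spliced:
        if splice_sites is None:
            raise ValueError("spliced implants require splice_sites=(donor, acceptor)")
        donor, acceptor = splice_sites
        body = body[:donor] + body[acceptor:]
    body, n_subs = _mutate(rng, body, sub_rate)
    strand = "+"
    interior = body + tail
    hb_len, tail_len = len(body), len(tail)
    if rng.random() < revcomp_prob:
        strand = "-"
        interior = revcomp(interior)
    seq = tsd + interior + tsd
    t = len(tsd)
    if strand == "+":
        hb = (t, t + hb_len)
        tl = (t + hb_len, t + hb_len + tail_len)
    else:  # tail sits at the genomic 5' side after reverse complementing
        tl = (t, t + tail_len)
        hb = (t + tail_len, t + tail_len + hb_len)
    truth = ImplantTruth(
        element_id=element_id,
        span=Interval("?", t, t + len(interior), strand),
        tsd_seq=tsd,
        tsd_left=Interval("?", 0, t),
        tsd_right=Interval("?", t + len(interior), len(seq)),
        headbody=Interval("?", hb[0], hb[1], strand),
        tail=Interval("?", tl[0], tl[1], strand),
        class_label="II" if spliced else "I",
        strand=strand,
        spliced=spliced,
        n_subs=n_subs,
    )
    return seq, [truth]


def implant_elements(
    background: GenomeSequence,
    consensus: str,
    n: int,
    tsd_len_range=(8, 20),
    tail_len_range=(10, 50),
    sub_rate: float = 0.0,
    tandem_prob: float = 0.0,
    nested_prob: float = 0.0,
    spliced_prob: float = 0.0,
    seed: int = 0,
    splice_sites: tuple[int, int] | None = None,
    tail_contamination: float = 0.1,
    revcomp_prob: float = 0.0,
    min_gap: int = 260,
    nested_location: str = "random",  # "random" | "body" | "tail"
) -> tuple[GenomeSequence, list[ImplantTruth]]:
    """Implant ``n`` element copies with TSDs, tails and structure variants.

    Each implant is TSD + (mutated, optionally spliced) head–body +
    poly(A) tail + TSD at a uniformly chosen non-overlapping site.
    Tandem implants share one outer TSD pair; nested implants carry a
    full element inside the host body or tail. Flanking background bases
    are adjusted so the implanted TSD is the *maximal* duplication,
    keeping the truth boundary well defined.
    """
    if tsd_len_range[0] > tsd_len_range[1] or tail_len_range[0] > tail_len_range[1]:
        raise ValueError("inverted length range")
    if spliced_prob > 0 and splice_sites is None:
        raise ValueError("spliced_prob > 0 requires splice_sites")
    rng = np.random.default_rng(seed)
    max_span = (
        2 * tsd_len_range[1] + len(consensus) + tail_len_range[1]
    )
    if n * max_span >= len(background.sequence) / 2:
        raise ValueError("background too small for the requested implants")

    inserts: list[_Insert] = []
    made = 0
    next_group = 0
    single_args = (
        tsd_len_range,
        tail_len_range,
        sub_rate,
        spliced_prob,
        splice_sites,
        tail_contamination,
        revcomp_prob,
    )
    while made < n:
        r = rng.random()
        if r < tandem_prob and n - made >= 2:
            # two interiors between one shared outer TSD pair
            tsd = _random_tsd(rng, int(rng.integers(tsd_len_range[0], tsd_len_range[1] + 1)))
            members: list[ImplantTruth] = []
            interior_parts: list[str] = []
            offset = len(tsd)
            for _ in range(2):
                s, tr = _single_unit(rng, consensus, f"e{made:04d}", *single_args)
                made += 1
                t = tr[0]
                inner_len = t.span.length  # body + tail
                inner = s[t.span.start : t.span.end]
                members.append(
                    replace(
                        t,
                        tsd_seq=tsd,
                        span=Interval("?", offset, offset + inner_len, t.strand),
                        headbody=t.headbody.shift(offset - t.span.start),
                        tail=t.tail.shift(offset - t.span.start),
                        tandem_group=next_group,
                    )
                )
                interior_parts.append(inner)
                offset += inner_len
            seq = tsd + "".join(interior_parts) + tsd
            left = Interval("?", 0, len(tsd))
            right = Interval("?", len(seq) - len(tsd), len(seq))
            members = [replace(m, tsd_left=left, tsd_right=right) for m in members]
            inserts.append(_Insert(0, seq, members))
            next_group += 1
        elif r < tandem_prob + nested_prob and n - made >= 2:
            host_seq, host_tr = _single_unit(rng, consensus, f"e{made:04d}", *single_args)
            host = host_tr[0]
            made += 1
            inner_seq, inner_tr = _single_unit(rng, consensus, f"e{made:04d}", *single_args)
            inner = inner_tr[0]
            made += 1
            # insertion point strictly inside the host body or tail
            into_tail = (
                nested_location == "tail"
                or (nested_location == "random" and rng.random() < 0.5)
            ) and host.tail.length > 2
            if into_tail:
                at = int(rng.integers(host.tail.start + 1, host.tail.end))
            else:
                at = int(rng.integers(host.headbody.start + 1, host.headbody.end))
            seq = host_seq[:at] + inner_seq + host_seq[at:]
            shift = len(inner_seq)

            def bump(iv: Interval) -> Interval:
                if iv.end <= at:
                    return iv
                if iv.start >= at:
                    return iv.shift(shift)
                return Interval(iv.chrom, iv.start, iv.end + shift, iv.strand)

            host = replace(
                host,
                span=bump(host.span),
                tsd_left=bump(host.tsd_left),
                tsd_right=bump(host.tsd_right),
                headbody=bump(host.headbody),
                tail=bump(host.tail),
            )
            inner = replace(
                inner,
                span=inner.span.shift(at),
                tsd_left=inner.tsd_left.shift(at),
                tsd_right=inner.tsd_right.shift(at),
                headbody=inner.headbody.shift(at),
                tail=inner.tail.shift(at),
                nested_parent=host.element_id,
            )
            inserts.append(_Insert(0, seq, [host, inner]))
        else:
            seq, tr = _single_unit(rng, consensus, f"e{made:04d}", *single_args)
            made += 1
            inserts.append(_Insert(0, seq, tr))

    # choose non-overlapping background positions with a safety margin
    positions: list[int] = []
    placed: list[tuple[int, int]] = []  # (pos, insert length)
    limit = len(background.sequence) - 1
    for ins in inserts:
        for _ in range(10000):
            p = int(rng.integers(min_gap, limit - min_gap))
            if all(
                p + len(ins.seq) + min_gap <= q or q + L + min_gap <= p
                for q, L in placed
            ):
                positions.append(p)
                placed.append((p, len(ins.seq)))
                break
        else:
            raise RuntimeError("could not place all implants without overlap")
    order = np.argsort(positions)
    chrom = background.name
    pieces: list[str] = []
    truths: list[ImplantTruth] = []
    cursor = 0
    offset = 0
    bg = background.sequence
    for idx in order:
        ins = inserts[idx]
        p = positions[idx]
        pieces.append(bg[cursor:p])
        start = p + offset
        for t in ins.truths:
            truths.append(
                replace(
                    t,
                    span=Interval(chrom, *_sh(t.span, start)),
                    tsd_left=Interval(chrom, *_sh(t.tsd_left, start)),
                    tsd_right=Interval(chrom, *_sh(t.tsd_right, start)),
                    headbody=Interval(chrom, *_sh(t.headbody, start), t.strand),
                    tail=Interval(chrom, *_sh(t.tail, start), t.strand),
                )
            )
        pieces.append(ins.seq)
        cursor = p
        offset += len(ins.seq)
    pieces.append(bg[cursor:])
    genome_seq = list("".join(pieces))

    # make each implanted TSD the maximal duplication: break accidental
    # one-base extensions by editing the adjacent *background* base
    for t in truths:
        if t.nested_parent is not None:
            # flanks of an inner element are host sequence, not background
            continue
        lb = t.tsd_left.start - 1
        rb = t.tsd_right.start - 1
        if lb >= 0 and genome_seq[lb] == genome_seq[rb]:
            genome_seq[lb] = _other_base(genome_seq[lb], rng)
        la = t.tsd_left.end
        ra = t.tsd_right.end
        if ra < len(genome_seq) and genome_seq[la] == genome_seq[ra]:
            genome_seq[ra] = _other_base(genome_seq[ra], rng)
    genome = GenomeSequence(chrom, "".join(genome_seq))
    truths.sort(key=lambda t: t.span.start)
    return genome, truths


def _sh(iv: Interval, offset: int) -> tuple[int, int]:
    return iv.start + offset, iv.end + offset


def _other_base(b: str, rng: np.random.Generator) -> str:
    options = [x for x in "ACGT" if x != b]
    return options[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# Annotation synthesis
# ---------------------------------------------------------------------------

def _mk_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    utr5: tuple[int, int] | None,
    utr3: tuple[int, int] | None,
) -> GeneModel:
    exons = sorted(exons)
    span = Interval(chrom, exons[0][0], exons[-1][1], strand)
    feats: dict[str, list[Interval]] = {
        "gene": [span],
        "exon": [Interval(chrom, s, e, strand) for s, e in exons],
    }
    utrs = []
    if utr5:
        feats["five_prime_utr"] = [Interval(chrom, *utr5, strand)]
        utrs.append(utr5)
    if utr3:
        feats["three_prime_utr"] = [Interval(chrom, *utr3, strand)]
        utrs.append(utr3)
    cds: list[Interval] = []
    for s, e in exons:
        cur = [(s, e)]
        for us, ue in utrs:
            nxt = []
            for cs, ce in cur:
                if ue <= cs or us >= ce:
                    nxt.append((cs, ce))
                else:
                    if cs < us:
                        nxt.append((cs, us))
                    if ue < ce:
                        nxt.append((ue, ce))
            cur = nxt
        cds.extend(Interval(chrom, cs, ce, strand) for cs, ce in cur if ce > cs)
    feats["CDS"] = cds
    tss = span.start if strand == "+" else span.end - 1
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, features=feats)


def synthesize_annotation(
    genome: GenomeSequence,
    truth: list[ImplantTruth],
    n_genes: int,
    exon_in_element_prob: float = 0.4,
    seed: int = 0,
    consensus_spec: ConsensusSpec = ConsensusSpec(),
    n_rna_genes: int = 2,
) -> list[GeneModel]:
    """Place genes so that downstream selection rules have work to do.

    A configurable fraction of genes has an internal exon boundary
    inside an element, preferentially at the element's dual-function
    AG|GT offsets (so the adjacent genomic dinucleotides are canonical);
    the rest are placed with an element 1–2 kb (proximal) or 2–100 kb
    (distal) upstream of the TSS.
    """
    rng = np.random.default_rng(seed)
    G = len(genome.sequence)
    if G < 4000 * max(n_genes, 1):
        raise ValueError("genome too small for the requested number of genes")
    occupied: list[tuple[int, int]] = []

    def free(s: int, e: int, margin: int = 200) -> bool:
        return 0 <= s < e <= G and all(e + margin <= os or oe + margin <= s for os, oe in occupied)

    element_blocks = [(t.tsd_left.start, t.tsd_right.end) for t in truth]

    def clear_of_elements(s: int, e: int) -> bool:
        return all(e <= bs or be <= s for bs, be in element_blocks)

    spec = consensus_spec
    donor_off = spec.head_len + spec.donor_offset
    acceptor_off = spec.head_len + spec.repeat_len + spec.acceptor_offset
    plus_elements = [t for t in truth if t.strand == "+" and not t.spliced]
    unused = list(plus_elements)
    rng.shuffle(unused)
    genes: list[GeneModel] = []
    gi = 0
    attempts = 0
    while gi < n_genes and attempts < 50 * n_genes:
        attempts += 1
        exonize = rng.random() < exon_in_element_prob and unused
        if exonize:
            t = unused[-1]
            hb = t.headbody.start
            donor_g = hb + donor_off
            acceptor_g = hb + acceptor_off
            seq = genome.sequence
            mode = None
            if seq[donor_g : donor_g + 2] == "GT" and rng.random() < 0.5:
                mode = "donor"
            elif seq[acceptor_g - 2 : acceptor_g] == "AG":
                mode = "acceptor"
            elif seq[donor_g : donor_g + 2] == "GT":
                mode = "donor"
            if mode is None:
                unused.pop()
                continue
            if mode == "donor":
                # middle exon crosses into the element and ends at the donor
                e2 = (t.span.start - 60, donor_g)
                e3s = t.tsd_right.end + 150
                e1 = (e2[0] - 400, e2[0] - 250)
                e3 = (e3s, e3s + 200)
            else:
                # middle exon starts at the acceptor and leaves the element
                e2 = (acceptor_g, t.tsd_right.end + 60)
                e1 = (t.span.start - 500, t.span.start - 350)
                e3 = (e2[1] + 250, e2[1] + 450)
            span = (e1[0], e3[1])
            if not free(*span) or not clear_of_elements(*e1) or not clear_of_elements(*e3):
                unused.pop()
                continue
            utr5 = (e1[0], e1[0] + 50)
            utr3 = (e3[1] - 50, e3[1])
            genes.append(_mk_gene(f"g{gi:03d}", genome.name, "+", [e1, e2, e3], utr5, utr3))
            occupied.append(span)
            unused.pop()
            gi += 1
        else:
            # gene with an element upstream: proximal (1-2 kb) or distal (2-100 kb)
            pool = [t for t in truth if t.tandem_group is None and t.nested_parent is None]
            t = pool[int(rng.integers(len(pool)))]
            mid = t.span.midpoint
            if rng.random() < 0.5:
                dist = int(rng.integers(1100, 1900))
            else:
                dist = int(rng.integers(2200, min(20000, G // 4)))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(1500, 3000))
            if strand == "+":
                s = mid + dist
                e = s + glen
            else:
                e = mid - dist
                s = e - glen
            if not free(s, e) or not clear_of_elements(s, e):
                continue
            mid_exon = (s + glen // 2 - 100, s + glen // 2 + 100)
            exons = [(s, s + 200), mid_exon, (e - 200, e)]
            if strand == "+":
                utr5, utr3 = (s, s + 50), (e - 50, e)
            else:
                utr5, utr3 = (e - 50, e), (s, s + 50)
            genes.append(_mk_gene(f"g{gi:03d}", genome.name, strand, exons, utr5, utr3))
            occupied.append((s, e))
            gi += 1
    if gi < n_genes:
        raise RuntimeError("could not place all genes; genome too crowded")
    for r in range(n_rna_genes):
        for _ in range(1000):
            s = int(rng.integers(0, G - 400))
            if free(s, s + 300) and clear_of_elements(s, s + 300):
                iv = Interval(genome.name, s, s + 300, "+")
                genes.append(
                    GeneModel(
                        gene_id=f"rna{r:02d}",
                        chrom=genome.name,
                        strand="+",
                        tss=s,
                        features={"rna_gene": [iv], "gene": [iv]},
                    )
                )
                occupied.append((s, s + 300))
                break
    return genes


# ---------------------------------------------------------------------------
# Methylome and expression simulation
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SimulatedMethylome:
    """Per-sample CpG tables plus the truth needed to grade recovery."""

    records: dict[str, list[MethylationRecord]]  # sample_id -> records
    design: list[tuple[str, str, str]]  # (sample_id, individual, tissue)
    element_true_means: dict[tuple[str, str], float]  # (element_id, sample_id)
    dm_truth: dict[str, float]  # element_id -> signed delta (tissue2 - tissue1)
    element_cpgs: dict[str, list[int]] = field(default_factory=dict)


def simulate_methylomes(
    genome: GenomeSequence,
    truth: list[ImplantTruth],
    genes: list[GeneModel] | None = None,
    n_individuals: int = 8,
    tissues: tuple[str, str] = ("muscle", "testis"),
    depth_range: tuple[int, int] = (10, 60),
    background_mean: float = 0.85,
    dm_fraction: float = 0.3,
    delta: float = 0.4,
    overdispersion: float = 0.05,
    indiv_sd: float = 0.2,
    n_background_cpgs: int = 200,
    dm_elements: list[str] | None = None,
    seed: int = 0,
) -> SimulatedMethylome:
    """Paired beta-binomial methylomes with a hypermethylated background.

    DM elements (drawn from proximal elements when an annotation is
    given) have mean ``background_mean − delta`` in the second tissue.
    A per-individual random effect on the logit scale induces the
    paired structure.
    """
    if not (0 <= delta <= 1):
        raise ValueError("delta must be in [0,1]")
    if background_mean - delta < 0:
        raise ValueError("background_mean - delta is negative")
    if depth_range[0] > depth_range[1]:
        raise ValueError("inverted depth range")
    rng = np.random.default_rng(seed)
    seq = genome.sequence

    element_cpgs: dict[str, list[int]] = {}
    covered: list[tuple[int, int]] = []
    for t in truth:
        positions = [
            p for p in range(t.span.start, t.span.end - 1) if seq[p : p + 2] == "CG"
        ]
        element_cpgs[t.element_id] = positions
        covered.append((t.span.start, t.span.end))
    covered.sort()

    def in_element(p: int) -> bool:
        import bisect

        i = bisect.bisect_right(covered, (p, 10**12)) - 1
        return i >= 0 and covered[i][0] <= p < covered[i][1]

    all_cg = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG" and not in_element(i)]
    if all_cg and n_background_cpgs:
        take = min(n_background_cpgs, len(all_cg))
        bg_cpgs = sorted(rng.choice(len(all_cg), size=take, replace=False))
        bg_positions = [all_cg[i] for i in bg_cpgs]
    else:
        bg_positions = []

    if dm_elements is None:
        if genes is not None:
            from sinescope.calibration import position_annotation

            cats = position_annotation([t.span for t in truth], genes)
            proximal = [
                truth[i].element_id for i, c in enumerate(cats) if c.category == "proximal"
            ]
        else:
            proximal = [t.element_id for t in truth]
        k = int(round(dm_fraction * len(proximal)))
        dm_elements = (
            sorted(str(e) for e in rng.choice(proximal, size=k, replace=False)) if k else []
        )
    dm_set = set(dm_elements)
    dm_truth = {e: -delta for e in dm_set}

    design: list[tuple[str, str, str]] = []
    records: dict[str, list[MethylationRecord]] = {}
    for i in range(n_individuals):
        for tis in tissues:
            sid = f"{tis}_{i + 1}"
            design.append((sid, f"ind{i + 1}", tis))
            records[sid] = []

    u = rng.normal(0.0, indiv_sd, size=n_individuals)
    element_true_means: dict[tuple[str, str], float] = {}
    base_logit = _logit(background_mean)

    def draw_counts(mean: float, n_sites: int):
        depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_sites)
        if overdispersion > 0:
            conc = (1 - overdispersion) / overdispersion
            a = max(mean * conc, 1e-9)
            b = max((1 - mean) * conc, 1e-9)
            p = rng.beta(a, b, size=n_sites)
        else:
            p = np.full(n_sites, mean)
        meths = rng.binomial(depths, p)
        return depths, meths

    for i in range(n_individuals):
        for tj, tis in enumerate(tissues):
            sid = f"{tis}_{i + 1}"
            recs = records[sid]
            for t in truth:
                positions = element_cpgs[t.element_id]
                mu = background_mean
                if t.element_id in dm_set and tj == 1:
                    mu = background_mean - delta
                m = _expit(_logit(mu) + u[i]) if 0 < mu < 1 else mu
                element_true_means[(t.element_id, sid)] = m
                if not positions:
                    continue
                depths, meths = draw_counts(m, len(positions))
                recs.extend(
                    MethylationRecord(genome.name, p, sid, tis, int(me), int(de))
                    for p, me, de in zip(positions, meths, depths)
                )
            if bg_positions:
                m = _expit(base_logit + u[i])
                depths, meths = draw_counts(m, len(bg_positions))
                recs.extend(
                    MethylationRecord(genome.name, p, sid, tis, int(me), int(de))
                    for p, me, de in zip(bg_positions, meths, depths)
                )
            recs.sort(key=lambda r: r.pos)
    return SimulatedMethylome(
        records=records,
        design=design,
        element_true_means=element_true_means,
        dm_truth=dm_truth,
        element_cpgs=element_cpgs,
    )


def simulate_expression(
    genes: list[GeneModel],
    meth: SimulatedMethylome,
    coupling: dict[str, str],
    beta: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    element_to_gene: dict[str, str] | None = None,
    truth: list[ImplantTruth] | None = None,
    baseline_mean: float = 3.0,
):
    """FPKM-like expression matrix with sign-coupled methylation effects.

    For a gene flanked by a coupled element, log-expression is
    baseline + sign·beta·(element methylation in that sample) + noise;
    values are exponentiated. Uncoupled genes get baseline + noise.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [sid for sid, _, _ in meth.design]
    if element_to_gene is None:
        if truth is None:
            raise ValueError("need element_to_gene or truth to resolve flanked genes")
        from sinescope.calibration import position_annotation

        cats = position_annotation([t.span for t in truth], genes)
        element_to_gene = {
            truth[i].element_id: c.nearest_gene
            for i, c in enumerate(cats)
            if c.nearest_gene is not None
        }
    for eid in coupling:
        if eid not in element_to_gene:
            raise ValueError(f"coupled element {eid} has no flanked gene")
    gene_effect: dict[str, tuple[str, str]] = {}
    for eid, sign in coupling.items():
        if sign not in ("+", "-", "0"):
            raise ValueError(f"invalid coupling sign {sign!r}")
        gene_effect[element_to_gene[eid]] = (eid, sign)
    data = {}
    coding = [g for g in genes if "rna_gene" not in g.features]
    baselines = {g.gene_id: baseline_mean + rng.normal(0, 1.0) for g in coding}
    for sid in samples:
        col = []
        for g in coding:
            x = baselines[g.gene_id] + rng.normal(0, noise_sd)
            if g.gene_id in gene_effect:
                eid, sign = gene_effect[g.gene_id]
                m = meth.element_true_means.get((eid, sid), 0.0)
                if sign == "+":
                    x += beta * m
                elif sign == "-":
                    x -= beta * m
            col.append(math.exp(x))
        data[sid] = col
    return pd.DataFrame(data, index=[g.gene_id for g in coding])
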