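"""Splice-signal enrichment on consensus coordinates and GU-AG excision.

Signals are exon boundaries falling inside elements, classified as
5' donors, 3' acceptors, or "T" (acceptor on the reverse-complement
strand relative to the element). Their positions are projected onto the
consensus through global alignment, profiled over the direct-repeat
window, and compared against a uniform sampling null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from sinescope.aligndist import global_align
from sinescope.calibration import CalibratedElement
from sinescope.io_formats import GeneModel, GenomeSequence, Interval


@dataclass(frozen=True)
class SpliceSignal:
    element_id: str
    element_offset: int  # 0-based offset on the element's own strand
    kind: str  # "5", "3", "T" (suffix "nc" for non-canonical)
    transcript_id: str
    consensus_pos: int | None = None  # 1-based consensus column

    @property
    def canonical(self) -> bool:
        return not self.kind.endswith("nc")


@dataclass(frozen=True)
class SpliceProfile:
    window: tuple[int, int]  # 1-based inclusive consensus positions
    counts: dict[int, int]

    @property
    def n_signals(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class NullThreshold:
    n_positions: int
    n_signals: int
    reps: int
    alpha: float
    k: int
    tail_prob_at_k: float


# ---------------------------------------------------------------------------
# Selection and marking
# ---------------------------------------------------------------------------

def _boundaries_inside(element: Interval, gene: GeneModel) -> list[tuple[int, str]]:
    """Exon boundaries strictly inside the element span.

    Returns (genomic boundary position, side) where side is "end" for
    an exon end (donor side on + transcripts) or "start".
    """
    out = []
    for exon in gene.features.get("exon", []):
        if exon.chrom != element.chrom:
            continue
        if element.start < exon.start < element.end:
            out.append((exon.start, "start"))
        if element.start < exon.end < element.end:
            out.append((exon.end, "end"))
    return out


def select_cds_partial_overlaps(
    elements: list[CalibratedElement],
    genes: list[GeneModel],
) -> list[CalibratedElement]:
    """Elements with an exon boundary inside them, overlapping CDS but
    neither UTR nor RNA-gene sequence."""
    kept = []
    for el in elements:
        span = el.full_span
        has_boundary = any(_boundaries_inside(span, g) for g in genes)
        if not has_boundary:
            continue
        bad = False
        has_cds = False
        for g in genes:
            for kind in ("five_prime_utr", "three_prime_utr", "rna_gene"):
                if any(span.overlaps(iv) for iv in g.features.get(kind, [])):
                    bad = True
            if any(span.overlaps(iv) for iv in g.features.get("CDS", [])):
                has_cds = True
        if bad or not has_cds:
            continue
        kept.append(el)
    return kept


def mark_splice_signals(
    element: CalibratedElement,
    genes: list[GeneModel],
    genome: GenomeSequence,
) -> list[SpliceSignal]:
    """Classify every exon boundary inside the element as a splice signal.

    Donor boundaries require GT immediately intronic of the exon end,
    acceptors AG immediately intronic of the exon start (on the
    transcript strand). Acceptors on the strand opposite the element are
    reported as kind T. Non-canonical boundaries get an "nc"-suffixed
    kind and are excluded from profiles by default.
    """
    span = element.full_span
    seq = genome.sequence
    eid = element.element_id or "el?"
    signals: list[SpliceSignal] = []
    for g in genes:
        for pos, side in _boundaries_inside(span, g):
            if g.strand != "-":
                if side == "end":  # donor: GT follows the exon
                    dinuc = seq[pos : pos + 2]
                    canonical = dinuc == "GT"
                    role = "5"
                    g0 = pos
                else:  # acceptor: AG precedes the exon
                    dinuc = seq[pos - 2 : pos]
                    canonical = dinuc == "AG"
                    role = "3"
                    g0 = pos - 2
            else:
                if side == "start":  # donor on -: intron is genomically left
                    dinuc = seq[pos - 2 : pos]
                    canonical = dinuc == "AC"  # revcomp(GT)
                    role = "5"
                    g0 = pos - 2
                else:  # acceptor on -: intron genomically right
                    dinuc = seq[pos : pos + 2]
                    canonical = dinuc == "CT"  # revcomp(AG)
                    role = "3"
                    g0 = pos
            if role == "3" and g.strand != element.strand:
                role = "T"
            if not canonical:
                role += "nc"
            if element.strand == "-":
                offset = span.end - (g0 + 2)
            else:
                offset = g0 - span.start
            signals.append(
                SpliceSignal(
                    element_id=eid,
                    element_offset=offset,
                    kind=role,
                    transcript_id=g.gene_id,
                )
            )
    signals.sort(key=lambda s: (s.element_offset, s.kind, s.transcript_id))
    return signals


# ---------------------------------------------------------------------------
# Projection and profiling
# ---------------------------------------------------------------------------

def project_to_consensus(
    signal: SpliceSignal,
    element_seq: str,
    consensus: str,
    max_distance: float = 0.5,
) -> SpliceSignal | None:
    """Translate an element offset to a 1-based consensus position.

    The element is globally aligned to the consensus; offsets landing on
    consensus-gap columns are pushed to the next non-gap consensus
    column 3'. Signals on elements too diverged (alignment distance ≥
    ``max_distance``) are dropped.
    """
    res = global_align(element_seq, consensus)
    if res.distance >= max_distance:
        return None
    e_off = -1
    c_pos = 0
    pending = signal.element_offset
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if cb != "-":
            c_pos += 1
        if ca != "-":
            e_off += 1
            if e_off == pending:
                if cb != "-":
                    return replace(signal, consensus_pos=c_pos)
                # inside an element-only insertion: next consensus column 3'
                return replace(signal, consensus_pos=c_pos + 1)
    return None


def signal_profile(signals: list[SpliceSignal], window: tuple[int, int]) -> SpliceProfile:
    """Counts per consensus position inside ``window`` (1-based inclusive).

    Non-canonical and unprojected signals are excluded.
    """
    counts: dict[int, int] = {}
    lo, hi = window
    for s in signals:
        if not s.canonical or s.consensus_pos is None:
            continue
        if lo <= s.consensus_pos <= hi:
            counts[s.consensus_pos] = counts.get(s.consensus_pos, 0) + 1
    return SpliceProfile(window=window, counts=counts)


def null_threshold(
    n_positions: int = 93,
    n_signals: int = 188,
    reps: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    method: str = "empirical",
) -> NullThreshold:
    """Hot-site threshold from a uniform sampling null.

    Each replicate drops ``n_signals`` uniformly into ``n_positions``;
    all (replicate, position) counts are pooled and k is the smallest
    integer with empirical P(count > k) ≤ alpha. ``method="exact"``
    uses the Binomial(n_signals, 1/n_positions) tail instead of
    sampling.
    """
    if n_positions <= 0 or n_signals <= 0 or alpha <= 0:
        raise ValueError("n_positions, n_signals and alpha must be positive")
    if method == "exact":
        from scipy.stats import binom

        dist = binom(n_signals, 1.0 / n_positions)
        k = 0
        while dist.sf(k) > alpha:
            k += 1
        return NullThreshold(n_positions, n_signals, 0, alpha, k, float(dist.sf(k)))
    if method != "empirical":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    p = np.full(n_positions, 1.0 / n_positions)
    counts = rng.multinomial(n_signals, p, size=reps).ravel()
    total = counts.size
    k = 0
    while True:
        tail = np.count_nonzero(counts > k) / total
        if tail <= alpha:
            return NullThreshold(n_positions, n_signals, reps, alpha, k, float(tail))
        k += 1


def null_counts(
    n_positions: int = 93,
    n_signals: int = 188,
    reps: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Pooled (replicate, position) counts of the sampling null."""
    rng = np.random.default_rng(seed)
    p = np.full(n_positions, 1.0 / n_positions)
    return rng.multinomial(n_signals, p, size=reps).ravel()


def hot_sites(
    profile: SpliceProfile,
    threshold: NullThreshold,
    inclusive: bool = False,
) -> list[int]:
    """Consensus positions whose count exceeds the null threshold.

    Default is the strict reading (count > k); ``inclusive`` switches to
    count ≥ k.
    """
    k = threshold.k
    if inclusive:
        return sorted(p for p, c in profile.counts.items() if c >= k)
    return sorted(p for p, c in profile.counts.items() if c > k)


# ---------------------------------------------------------------------------
# Dual-function sites and excision
# ---------------------------------------------------------------------------

def find_dual_sites(consensus_spec) -> list[tuple[int, int]]:
    """Donor/acceptor pairs of the dual-function AG|GT sites.

    For each adjacent pair of repeat copies (i, i+1): donor = GT start
    in copy i, acceptor = AG end in copy i+1, as 0-based offsets into
    the head-body consensus. Excising between a pair removes exactly one
    repeat unit's worth of sequence.
    """
    spec = consensus_spec
    u = spec.repeat_unit
    if (
        u[spec.donor_offset : spec.donor_offset + 2] != "GT"
        or u[spec.acceptor_offset - 2 : spec.acceptor_offset] != "AG"
    ):
        raise ValueError("repeat unit lacks the AG|GT dual-function site")
    pairs = []
    for i in range(spec.n_repeats - 1):
        donor = spec.head_len + i * spec.repeat_len + spec.donor_offset
        acceptor = spec.head_len + (i + 1) * spec.repeat_len + spec.acceptor_offset
        pairs.append((donor, acceptor))
    if not pairs:
        raise ValueError("need at least two repeat copies for a dual-site pairing")
    return pairs


def excise_by_splice(
    seq: str,
    donor_pos: int,
    acceptor_pos: int,
    check_branch: bool = False,
    branch_motif: str = "CTGAT",
) -> str:
    """Excise [donor, acceptor) following the GU-AG rule.

    Requires GT at the donor and AG immediately before the acceptor.
    With ``check_branch``, a branch-site motif (≤1 mismatch from
    ``branch_motif``) must occur inside the excised segment.
    """
    if donor_pos >= acceptor_pos:
        raise ValueError("donor must precede acceptor")
    if seq[donor_pos : donor_pos + 2] != "GT":
        raise ValueError(f"no GT donor at position {donor_pos}")
    if seq[acceptor_pos - 2 : acceptor_pos] != "AG":
        raise ValueError(f"no AG acceptor before position {acceptor_pos}")
    if check_branch:
        segment = seq[donor_pos:acceptor_pos]
        m = len(branch_motif)
        found = any(
            sum(a != b for a, b in zip(segment[i : i + m], branch_motif)) <= 1
            for i in range(0, len(segment) - m + 1)
        )
        if not found:
            raise ValueError("no branch-site motif in the excised segment")
    return seq[:donor_pos] + seq[acceptor_pos:]
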