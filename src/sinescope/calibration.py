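"""TSD-based calibration of element copies.

The boundary of a copy is defined by its target site duplication: an
8-mer anchored near the rough hit start is searched for an exact match
in the 3' flank and extended in both directions; the longest extended
duplication wins. Copies without a TSD fall back to the conserved
motif + poly(A) rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from sinescope.io_formats import GenomeSequence, GeneModel, Interval, revcomp

logger = logging.getLogger(__name__)

CONSERVED_MOTIF = "GGAGTTCCC"

#: head-body length bins for class assignment (midpoint cut between the
#: 231 and 185 modes)
CLASS_I_RANGE = (210, 260)
CLASS_II_RANGE = (165, 209)


@dataclass(frozen=True)
class RawHit:
    """A rough element match, from the built-in scanner or an external BED."""

    interval: Interval
    source: str = "scan"

    def __post_init__(self) -> None:
        if self.interval.length < 50:
            raise ValueError("raw hit shorter than 50 bp")


@dataclass(frozen=True)
class TSD:
    sequence: str
    left_span: Interval
    right_span: Interval

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CalibratedElement:
    full_span: Interval
    strand: str
    tsd: TSD | None
    headbody_span: Interval
    tail_span: Interval | None
    class_label: str  # I / II / other
    boundary_method: str  # tsd / motif_fallback
    element_id: str | None = None
    tandem_group: int | None = None
    nested_parent: str | None = None

    @property
    def headbody_length(self) -> int:
        return self.headbody_span.length

    @property
    def tail_length(self) -> int:
        return self.tail_span.length if self.tail_span else 0


@dataclass(frozen=True)
class PositionCategory:
    element_id: str
    category: str  # intragenic / proximal / distal / upstream_lt1kb / other
    nearest_gene: str | None
    midpoint_distance: int | None


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_hits(
    genome: GenomeSequence,
    consensus: str,
    word_size: int = 12,
    min_identity: float = 0.7,
    min_len: int = 100,
) -> list[RawHit]:
    """Seed-and-extend scan of the genome for copies of the consensus.

    Exact ``word_size``-mers seed diagonal clusters which are projected
    to the full query span and verified by global alignment identity.
    Both strands are searched; overlapping accepted hits are merged.
    Deterministic for fixed inputs.
    """
    from sinescope.aligndist import global_align

    if len(consensus) < word_size:
        raise ValueError("consensus shorter than word_size")
    seq = genome.sequence
    G = len(seq)
    accepted: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for strand in ("+", "-"):
        query = consensus if strand == "+" else revcomp(consensus)
        qlen = len(query)
        seeds: list[tuple[int, int]] = []  # (diag, tpos) with qpos = tpos - diag
        for qpos in range(0, qlen - word_size + 1):
            word = query[qpos : qpos + word_size]
            if "N" in word:
                continue
            for tpos in _find_all(seq, word):
                seeds.append((tpos - qpos, tpos))
        seeds.sort()
        clusters: list[list[tuple[int, int]]] = []
        for diag, tpos in seeds:
            if (
                clusters
                and diag - clusters[-1][-1][0] <= 20
                and (diag != clusters[-1][-1][0] or tpos - clusters[-1][-1][1] <= 100)
            ):
                clusters[-1].append((diag, tpos))
            else:
                clusters.append([(diag, tpos)])
        for cluster in clusters:
            # project the cluster to the full query span via its diagonals
            start = max(0, min(d for d, _ in cluster))
            end = min(G, max(d for d, _ in cluster) + qlen)
            if end - start < min_len:
                continue
            region = seq[start:end]
            res = global_align(region, query)
            identity = res.n_matches / res.n_columns
            if identity >= min_identity:
                accepted[strand].append((start, end))
    hits: list[RawHit] = []
    for strand, spans in accepted.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        hits.extend(
            RawHit(Interval(genome.name, s, e, strand), source="scan") for s, e in merged
        )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def hits_from_bed(intervals: list[Interval]) -> list[RawHit]:
    return [RawHit(iv, source="bed") for iv in intervals]


# ---------------------------------------------------------------------------
# TSD search
# ---------------------------------------------------------------------------

def find_tsd(
    genome: GenomeSequence,
    hit: "RawHit | Interval",
    flank: int = 200,
    seed_k: int = 8,
    search_window: tuple[int, int] = (-30, 15),
    back: int = 60,
) -> TSD | None:
    """Locate the target site duplication delimiting a rough hit.

    Every ``seed_k``-mer whose start lies within ``search_window`` of
    the hit start is searched for an exact match in the 3' flank (hit
    end to hit end + ``flank``); matches are extended in both directions
    while bases agree. The longest extended duplication is returned,
    ties going to the candidate whose left copy starts most 5'.
    Candidates containing N are discarded (exact match is undefined).

    ``back`` lets the 3' search start slightly before the hit end, so
    rough hits that overshoot the element (e.g. a full-length query
    matched to a copy missing one repeat unit) still reach their TSD.
    """
    iv = hit.interval if isinstance(hit, RawHit) else hit
    seq = genome.sequence
    G = len(seq)
    if iv.strand == "-":
        # mirror the search: run the + logic on the reverse complement of
        # a local window, then map the spans back to genome coordinates
        win_lo = max(0, iv.start - flank - 100)
        win_hi = min(G, iv.end + flank + 100)
        local = GenomeSequence(genome.name, revcomp(seq[win_lo:win_hi]))
        wlen = win_hi - win_lo
        flipped = Interval(iv.chrom, wlen - (iv.end - win_lo), wlen - (iv.start - win_lo), "+")
        res = find_tsd(local, flipped, flank=flank, seed_k=seed_k,
                       search_window=search_window, back=back)
        if res is None:
            return None

        def back_map(span: Interval) -> Interval:
            return Interval(iv.chrom, win_lo + wlen - span.end, win_lo + wlen - span.start)

        left = back_map(res.right_span)  # genome-leftmost copy
        right = back_map(res.left_span)
        return TSD(sequence=seq[left.start : left.end], left_span=left, right_span=right)
    right_start = max(iv.start + 50, iv.end - back)
    right_end = min(G, iv.end + flank)
    if right_end - right_start < seed_k:
        return None
    region = seq[right_start:right_end]
    best: tuple[int, int, int] | None = None  # (length, left_start, right_start)
    lo = max(0, iv.start + search_window[0])
    hi = min(G - seed_k, iv.start + search_window[1])
    for s in range(lo, hi + 1):
        kmer = seq[s : s + seed_k]
        if "N" in kmer:
            continue
        for off in _find_all(region, kmer):
            r = right_start + off
            l0, r0, L = s, r, seed_k
            while (
                l0 > 0
                and r0 > 0
                and seq[l0 - 1] == seq[r0 - 1]
                and seq[l0 - 1] != "N"
                and r0 - 1 >= l0 + L
            ):
                l0 -= 1
                r0 -= 1
                L += 1
            while (
                l0 + L < G
                and r0 + L < G
                and seq[l0 + L] == seq[r0 + L]
                and seq[l0 + L] != "N"
                and l0 + L < r0
            ):
                L += 1
            if best is None or L > best[0]:
                best = (L, l0, r0)
    if best is None:
        return None
    L, l0, r0 = best
    return TSD(
        sequence=seq[l0 : l0 + L],
        left_span=Interval(iv.chrom, l0, l0 + L),
        right_span=Interval(iv.chrom, r0, r0 + L),
    )


# ---------------------------------------------------------------------------
# Head-body / tail split
# ---------------------------------------------------------------------------

def split_headbody_tail(
    element_seq: str,
    min_headbody: int = 150,
    motif: str = CONSERVED_MOTIF,
) -> tuple[tuple[int, int], tuple[int, int], str]:
    """Split an element (5'→3') into head–body and tail.

    The boundary is the start of the first AAAA run at or after
    ``min_headbody``; failing that, the first poly(A) run (≥6 bases, one
    mismatch allowed) after the conserved motif (method
    ``motif_fallback``); failing both the tail is empty (method
    ``none``). Returns ((0, boundary), (boundary, len), method).
    """
    L = len(element_seq)
    if L < min_headbody:
        raise ValueError(f"element of length {L} shorter than min_headbody={min_headbody}")
    i = element_seq.find("AAAA", min_headbody)
    if i != -1:
        return (0, i), (i, L), "aaaa"
    m = element_seq.find(motif)
    if m != -1:
        for j in range(m + len(motif), L - 5):
            w = element_seq[j : j + 6]
            if w[0] == "A" and w.count("A") >= 5:
                return (0, j), (j, L), "motif_fallback"
    return (0, L), (L, L), "none"


def _polya_run_end(seq: str, start: int, max_scan: int = 80) -> int:
    """End of the A-rich run beginning at ``start`` (A-fraction ≥ 0.8)."""
    best = start
    a = 0
    for j in range(start, min(len(seq), start + max_scan)):
        if seq[j] == "A":
            a += 1
        if seq[j] == "A" and a / (j - start + 1) >= 0.8:
            best = j + 1
    return best


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class CalibrationError(ValueError):
    pass


def calibrate(
    genome: GenomeSequence,
    hit: "RawHit | Interval",
    flank: int = 200,
    seed_k: int = 8,
    search_window: tuple[int, int] = (-30, 15),
    min_headbody: int = 150,
    motif: str = CONSERVED_MOTIF,
    min_full_len: int = 50,
) -> CalibratedElement:
    """Resolve exact element boundaries for one rough hit.

    With a TSD the full span is the distance between the two copies;
    otherwise the conserved-motif fallback delimits it. Raises
    :class:`CalibrationError` (with a reason) for unresolvable hits.
    """
    iv = hit.interval if isinstance(hit, RawHit) else hit
    strand = iv.strand if iv.strand in "+-" else "+"
    seq = genome.sequence
    tsd = find_tsd(genome, iv, flank=flank, seed_k=seed_k, search_window=search_window)
    if tsd is not None and tsd.right_span.start - tsd.left_span.end >= min_full_len:
        full = Interval(iv.chrom, tsd.left_span.end, tsd.right_span.start, strand)
        method = "tsd"
    else:
        tsd = None
        method = "motif_fallback"
        if strand == "+":
            ext = seq[iv.start : min(len(seq), iv.end + flank)]
            (hs, he), (ts, _), split_method = split_headbody_tail(ext, min_headbody, motif)
            if split_method == "none":
                raise CalibrationError("no TSD and no tail boundary found")
            tail_end = _polya_run_end(ext, ts)
            full = Interval(iv.chrom, iv.start, iv.start + max(tail_end, he), strand)
        else:
            win_start = max(0, iv.start - flank)
            ext = revcomp(seq[win_start : iv.end])
            (hs, he), (ts, _), split_method = split_headbody_tail(ext, min_headbody, motif)
            if split_method == "none":
                raise CalibrationError("no TSD and no tail boundary found")
            tail_end = _polya_run_end(ext, ts)
            full = Interval(iv.chrom, iv.end - max(tail_end, he), iv.end, strand)
    if full.length < min_full_len:
        raise CalibrationError(f"calibrated span of {full.length} bp below {min_full_len}")
    element_seq = seq[full.start : full.end]
    if strand == "-":
        element_seq = revcomp(element_seq)
    (hs, he), (ts, te), _sm = split_headbody_tail(element_seq, min_headbody, motif)
    if te == ts:
        raise CalibrationError("no poly(A) tail boundary inside the calibrated span")
    # the split must leave a credible (A-rich) tail; advance to later AAAA
    # boundaries if the first one exposes non-tail sequence (e.g. a nested
    # insertion inside the host interior)
    while element_seq[ts:te].count("A") / (te - ts) < 0.6:
        nxt = element_seq.find("AAAA", ts + 1)
        if nxt == -1:
            raise CalibrationError("tail region is not A-rich; not a credible element")
        hs, he, ts = 0, nxt, nxt
    if strand == "+":
        hb = Interval(iv.chrom, full.start + hs, full.start + he, strand)
        tail = Interval(iv.chrom, full.start + ts, full.start + te, strand) if te > ts else None
    else:
        hb = Interval(iv.chrom, full.end - he, full.end - hs, strand)
        tail = Interval(iv.chrom, full.end - te, full.end - ts, strand) if te > ts else None
    hb_len = hb.length
    if CLASS_I_RANGE[0] <= hb_len <= CLASS_I_RANGE[1]:
        label = "I"
    elif CLASS_II_RANGE[0] <= hb_len <= CLASS_II_RANGE[1]:
        label = "II"
    else:
        label = "other"
    return CalibratedElement(
        full_span=full,
        strand=strand,
        tsd=tsd,
        headbody_span=hb,
        tail_span=tail,
        class_label=label,
        boundary_method=method,
    )


def calibrate_all(
    genome: GenomeSequence,
    hits: list["RawHit | Interval"],
    **kwargs,
) -> tuple[list[CalibratedElement], list[tuple[Interval, str]]]:
    """Calibrate a batch of hits; rejected hits are returned with reasons."""
    elements: list[CalibratedElement] = []
    rejected: list[tuple[Interval, str]] = []
    for hit in hits:
        iv = hit.interval if isinstance(hit, RawHit) else hit
        try:
            elements.append(calibrate(genome, hit, **kwargs))
        except (CalibrationError, ValueError) as exc:
            rejected.append((iv, str(exc)))
    for i, el in enumerate(elements):
        elements[i] = replace(el, element_id=f"el{i:04d}")
    return elements, rejected


# ---------------------------------------------------------------------------
# Structure detection and positional annotation
# ---------------------------------------------------------------------------

def detect_structures(
    elements: list[CalibratedElement],
    genome: GenomeSequence | None = None,
    max_gap: int = 10,
    flank: int = 200,
) -> list[CalibratedElement]:
    """Flag tandem groups and nested elements.

    Tandem: maximal runs of same-chromosome elements separated by at
    most ``max_gap`` bp that share an outer TSD pair (verified on the
    genome when provided). Nested: full span strictly inside another
    element's. Output order follows input order.
    """
    order = sorted(range(len(elements)), key=lambda i: (elements[i].full_span.chrom, elements[i].full_span.start, elements[i].full_span.end))
    flags: dict[int, dict] = {i: {} for i in range(len(elements))}
    # tandem runs
    group_id = 0
    run: list[int] = []

    def close_run() -> None:
        nonlocal group_id
        if len(run) >= 2:
            chrom = elements[run[0]].full_span.chrom
            start = elements[run[0]].full_span.start
            end = elements[run[-1]].full_span.end
            ok = False
            if genome is not None:
                pseudo = Interval(chrom, start, end)
                tsd = find_tsd(genome, pseudo, flank=flank)
                # the outer pair must flank the whole run; allow a few bp of
                # slack for fallback boundaries that overshoot into a TSD
                ok = (
                    tsd is not None
                    and tsd.left_span.end <= start + 5
                    and tsd.right_span.start >= end - 45
                )
            if ok:
                for i in run:
                    flags[i]["tandem_group"] = group_id
                group_id += 1
        run.clear()

    prev = None
    for i in order:
        el = elements[i]
        gap = (
            el.full_span.start - elements[prev].full_span.end if prev is not None else None
        )
        if (
            prev is not None
            and el.full_span.chrom == elements[prev].full_span.chrom
            and gap <= max_gap
            and gap >= -40  # tolerate small fallback-boundary overshoot
            and not elements[prev].full_span.contains(el.full_span)
        ):
            run.append(i)
        else:
            close_run()
            run.append(i)
        prev = i
    close_run()
    # nesting
    for i in order:
        for j in order:
            if i == j:
                continue
            if elements[j].full_span.strictly_contains(elements[i].full_span):
                pid = elements[j].element_id or f"el{j:04d}"
                flags[i]["nested_parent"] = pid
                break
    return [replace(el, **flags[i]) for i, el in enumerate(elements)]


def position_annotation(
    elements: "list[CalibratedElement] | list[Interval]",
    genes: list[GeneModel],
) -> list[PositionCategory]:
    """Categorize elements relative to genes (strand-aware upstream bins).

    Overlap with any gene span → intragenic; otherwise the midpoint
    distance to the nearest upstream TSS is binned: <1 kb, [1,2) kb
    (proximal), [2,100] kb (distal), else other.
    """
    out: list[PositionCategory] = []
    for idx, el in enumerate(elements):
        span = el.full_span if isinstance(el, CalibratedElement) else el
        eid = (
            el.element_id
            if isinstance(el, CalibratedElement) and el.element_id
            else f"el{idx:04d}"
        )
        mid = span.midpoint
        hit_gene = None
        for g in genes:
            if span.overlaps(g.span):
                hit_gene = g
                break
        if hit_gene is not None:
            out.append(PositionCategory(eid, "intragenic", hit_gene.gene_id, 0))
            continue
        best_d: int | None = None
        best_gene: str | None = None
        for g in genes:
            if g.chrom != span.chrom:
                continue
            if g.strand == "-":
                d = mid - g.tss
            else:
                d = g.tss - mid
            if d <= 0:
                continue
            if best_d is None or d < best_d:
                best_d, best_gene = d, g.gene_id
        if best_d is None:
            out.append(PositionCategory(eid, "other", None, None))
        elif best_d < 1000:
            out.append(PositionCategory(eid, "upstream_lt1kb", best_gene, best_d))
        elif best_d < 2000:
            out.append(PositionCategory(eid, "proximal", best_gene, best_d))
        elif best_d <= 100_000:
            out.append(PositionCategory(eid, "distal", best_gene, best_d))
        else:
            out.append(PositionCategory(eid, "other", best_gene, best_d))
    return out
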