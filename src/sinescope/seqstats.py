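"""Composition statistics, CpG islands, divergence and the molecular clock."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from sinescope import aligndist

#: substitution rate per site per year used for the molecular clock
DEFAULT_ALPHA = 4.6e-9


@dataclass(frozen=True)
class CompositionStats:
    """Base composition of one sequence (N bases excluded everywhere)."""

    length: int
    gc: float
    n_cpg: int
    n_c: int
    n_g: int
    oe: float
    oe_defined: bool


@dataclass(frozen=True)
class DivergenceEstimate:
    """Per-site divergence D and the clock time t = D/(2·alpha)."""

    d: float
    alpha: float
    t_years: float

    @property
    def t_mya(self) -> float:
        return self.t_years / 1e6


@dataclass(frozen=True)
class DiversityStat:
    pi: float
    n_seqs: int
    n_sites_used: int


def composition(seq: str) -> CompositionStats:
    """Length, GC, CpG count and the Gardiner–Garden observed/expected ratio.

    The O/E ratio is n_cpg·L/(n_c·n_g); when either C or G is absent the
    ratio is reported as 0 with ``oe_defined`` false.
    """
    if not seq:
        raise ValueError("empty sequence")
    core = seq.upper()
    length = sum(1 for b in core if b != "N")
    if length == 0:
        raise ValueError("sequence is all N")
    n_c = core.count("C")
    n_g = core.count("G")
    n_cpg = core.count("CG")
    gc = (n_c + n_g) / length
    if n_c * n_g > 0:
        oe = n_cpg * length / (n_c * n_g)
        defined = True
    else:
        oe, defined = 0.0, False
    return CompositionStats(
        length=length, gc=gc, n_cpg=n_cpg, n_c=n_c, n_g=n_g, oe=oe, oe_defined=defined
    )


def is_cpg_island(stats: CompositionStats) -> bool:
    """CpG-island predicate: length ≥ 200, GC ≥ 0.5, O/E strictly > 0.6."""
    return stats.length >= 200 and stats.gc >= 0.5 and stats.oe > 0.6


def p_distance(
    seq_a: str,
    seq_b: str,
    aligned: bool = False,
    jukes_cantor: bool = False,
) -> float:
    """Base changes per site (uncorrected p-distance, pairwise deletion).

    Gap-containing columns are excluded. When ``aligned`` is false the
    pair is globally aligned first. ``jukes_cantor`` applies the JC69
    correction −3/4·ln(1 − 4p/3) on top.
    """
    if aligned:
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned sequences must have equal length")
        a, b = seq_a.upper(), seq_b.upper()
    else:
        res = aligndist.global_align(seq_a.upper(), seq_b.upper())
        a, b = res.aligned_a, res.aligned_b
    compared = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns")
    p = diffs / compared
    if jukes_cantor:
        if p >= 0.75:
            raise ValueError("p-distance too large for JC correction")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return p


def divergence_time(d: float, alpha: float = DEFAULT_ALPHA) -> DivergenceEstimate:
    """Molecular-clock divergence time t = D/(2·alpha), in years."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if d < 0:
        raise ValueError("D must be non-negative")
    return DivergenceEstimate(d=d, alpha=alpha, t_years=d / (2.0 * alpha))


def nucleotide_diversity(aligned_seqs: list[str]) -> DiversityStat:
    """Mean pairwise p-distance over all unordered pairs (pairwise deletion)."""
    if len(aligned_seqs) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one aligned length")
    dists = [
        p_distance(a, b, aligned=True)
        for a, b in itertools.combinations(aligned_seqs, 2)
    ]
    return DiversityStat(
        pi=sum(dists) / len(dists),
        n_seqs=len(aligned_seqs),
        n_sites_used=lengths.pop(),
    )


def consensus_from_alignment(aligned_seqs: list[str]) -> str:
    """Majority-rule consensus of an alignment.

    Columns with gap fraction ≥ 0.5 are dropped; ties are broken by the
    fixed base order A < C < G < T.
    """
    if not aligned_seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one aligned length")
    n = len(aligned_seqs)
    out = []
    for col in zip(*aligned_seqs):
        gaps = col.count("-")
        if gaps / n >= 0.5:
            continue
        best = max("ACGT", key=lambda b: (col.count(b), -"ACGT".index(b)))
        out.append(best)
    return "".join(out)
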