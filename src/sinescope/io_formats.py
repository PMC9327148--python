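"""Readers and writers for the standard formats used across the toolkit.

One coordinate convention is used internally everywhere: 0-based,
half-open intervals. Conversion to and from 1-based formats (GTF)
happens only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
IUPAC_EXTRA = frozenset("RYSWKMBDHV")  # folded to N on load

#: closed set of annotation feature kinds the toolkit understands
FEATURE_KINDS = frozenset(
    {"gene", "exon", "CDS", "five_prime_utr", "three_prime_utr", "rna_gene"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse-complement an uppercase DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/contig holding uppercase DNA over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval; strand '.' where irrelevant."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def strictly_contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.start
            and other.end < self.end
        )

    def shift(self, offset: int) -> "Interval":
        return Interval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class GeneModel:
    """A gene with per-kind feature intervals and a strand-aware TSS.

    ``features`` maps a kind from :data:`FEATURE_KINDS` to a list of
    intervals. Exons must lie within the gene span and CDS within exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    features: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.features) - FEATURE_KINDS
        if unknown:
            raise ValueError(f"unknown feature kinds {sorted(unknown)} in {self.gene_id}")

    @property
    def span(self) -> Interval:
        genes = self.features.get("gene")
        if genes:
            return genes[0]
        ivs = [iv for ivs in self.features.values() for iv in ivs]
        if not ivs:
            raise ValueError(f"gene {self.gene_id} has no intervals")
        return Interval(
            self.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs), self.strand
        )

    def exons(self) -> list[Interval]:
        return sorted(self.features.get("exon", []))


@dataclass(frozen=True)
class MethylationRecord:
    """Counts at one CpG (keyed to the C on the + strand) in one sample."""

    chrom: str
    pos: int
    sample_id: str
    tissue: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"bad counts n_meth={self.n_meth} n_total={self.n_total} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def level(self) -> float:
        """Methylation level in [0,1]; undefined (nan) at depth 0."""
        if self.n_total == 0:
            return float("nan")
        return self.n_meth / self.n_total


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Soft-masked (lowercase) bases are folded to uppercase; ambiguity
    codes are folded to N. Any other character is an error naming the
    offending line.
    """
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is not None:
            seq = "".join(chunks)
            if not seq:
                raise ValueError(f"record {name!r} has an empty sequence")
            records.append(GenomeSequence(name, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"sequence before header at line {lineno}")
                up = line.upper()
                cleaned = []
                for ch in up:
                    if ch in DNA_ALPHABET:
                        cleaned.append(ch)
                    elif ch in IUPAC_EXTRA:
                        cleaned.append("N")
                    else:
                        raise ValueError(
                            f"non-IUPAC character {ch!r} at line {lineno} of {path}"
                        )
                chunks.append("".join(cleaned))
    _flush()
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (Ensembl dialect)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into :class:`GeneModel` objects.

    1-based inclusive coordinates are converted to internal 0-based
    half-open. Feature kinds outside :data:`FEATURE_KINDS` are ignored
    (count logged). Order of genes follows first appearance.
    """
    genes: dict[str, GeneModel] = {}
    n_ignored = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"expected 9 GTF columns at line {lineno}")
            chrom, _source, kind, start_s, end_s, _score, strand, _frame, attr_s = fields
            if kind not in FEATURE_KINDS:
                n_ignored += 1
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"end < start at line {lineno}")
            attrs = _parse_gtf_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ValueError(f"missing gene_id at line {lineno}")
            iv = Interval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            model = genes.get(gene_id)
            if model is None:
                model = GeneModel(gene_id=gene_id, chrom=chrom, strand=iv.strand, tss=-1)
                genes[gene_id] = model
            model.features.setdefault(kind, []).append(iv)
    if n_ignored:
        logger.info("read_gtf: ignored %d records of unknown feature kind", n_ignored)
    for model in genes.values():
        span = model.span
        model.tss = span.start if model.strand != "-" else span.end - 1
    return list(genes.values())


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "sinescope") -> None:
    """Write gene models back out as Ensembl-style GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            for kind in ("gene", "exon", "CDS", "five_prime_utr", "three_prime_utr", "rna_gene"):
                for iv in gene.features.get(kind, []):
                    fh.write(
                        "\t".join(
                            [
                                iv.chrom,
                                source,
                                kind,
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand if iv.strand in "+-" else ".",
                                ".",
                                f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";',
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Methylation tables (bedGraph-with-counts dialect)
# ---------------------------------------------------------------------------

def read_methylation_table(
    path: str | Path,
    sample_id: str,
    tissue: str,
    destrand: bool = True,
) -> list[MethylationRecord]:
    """Read a bedGraph-with-counts methylation table.

    Expected columns: chrom, start, end, level (ignored), n_meth,
    n_total, and optionally strand. The start column is already 0-based
    and is used as the CpG position. When a strand column is present and
    ``destrand`` is true, records on the G (− strand) are folded onto
    the C position (start − 1) and counts summed.
    """
    raw: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"expected ≥6 columns at line {lineno} of {path}")
            chrom = fields[0]
            pos = int(fields[1])
            n_meth = int(fields[4])
            n_total = int(fields[5])
            if n_meth > n_total:
                raise ValueError(f"n_meth > n_total at line {lineno} of {path}")
            if destrand and len(fields) >= 7 and fields[6] == "-":
                pos -= 1
            key = (chrom, pos)
            if key in raw:
                raw[key][0] += n_meth
                raw[key][1] += n_total
            else:
                raw[key] = [n_meth, n_total]
                order.append(key)
    return [
        MethylationRecord(chrom, pos, sample_id, tissue, raw[(chrom, pos)][0], raw[(chrom, pos)][1])
        for chrom, pos in order
    ]


def write_methylation_table(records: Iterable[MethylationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            level = 0.0 if rec.n_total == 0 else 100.0 * rec.n_meth / rec.n_total
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t{level:.6g}\t{rec.n_meth}\t{rec.n_total}\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[Interval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6; internal coordinates emitted unchanged."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 into internal intervals (coordinates unchanged)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"expected ≥3 BED columns at line {lineno}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path):
    """Read a TSV expression matrix (rows = genes, columns = samples)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_matrix(matrix, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True)
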