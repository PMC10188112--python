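"""Fragment-level conventions and interval logic for ATAC/ChIP processing.

All coordinates are 0-based half-open [start, end), the BED convention.
The operations here encode the bespoke filtering and association rules of
the accessibility pipeline: the Tn5 insertion-site offset (+4 bp on the +
strand, −5 bp on the −), the effective-fragment filter (mapping quality
>= 30, insert size <= 100 bp), RPM coverage normalized to effective
fragments, condition-specific peak calls (called at a stringent threshold
in one condition, no overlapping call at a lenient threshold in the
other), and promoter association (peak overlapping ±1 kb of the TSS).
Overlap always means at least one shared base; abutting half-open
intervals do not overlap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "FragmentRecord",
    "GeneAnnotation",
    "shift_reads",
    "filter_fragments",
    "rpm_coverage",
    "condition_specific_peaks",
    "promoter_association",
    "tss_from_span",
    "read_bed",
    "write_bed",
    "read_fragment_bed",
    "write_fragment_bed",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class FragmentRecord:
    """A paired-end sequencing fragment with its mapping quality."""

    interval: GenomicInterval
    mapq: int
    name: str = "."
    is_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")

    @property
    def insert_size(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's transcription start site with strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene!r}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene!r}: tss must be non-negative")


def tss_from_span(start: int, end: int, strand: str) -> int:
    """TSS of a gene span: 5'-most base, i.e. ``start`` on the + strand and
    ``end − 1`` (the 3'-most coordinate of the half-open span) on −."""
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise ValueError(f"strand must be + or -, got {strand!r}")


def shift_reads(read: GenomicInterval) -> GenomicInterval:
    """Apply the Tn5 insertion-site offset to an aligned read.

    Reads on the + strand shift their start by +4 bp; reads on the − strand
    shift their end by −5 bp, recovering the actual transposase insertion
    points. A read the shift would collapse is rejected.
    """
    if read.strand == "+":
        new = (read.start + 4, read.end)
    elif read.strand == "-":
        new = (read.start, read.end - 5)
    else:
        raise ValueError(f"read {read} has no strand; cannot apply Tn5 shift")
    if new[0] >= new[1]:
        raise ValueError(f"Tn5 shift collapses read {read}")
    return replace(read, start=new[0], end=new[1])


def filter_fragments(
    frags: Iterable[FragmentRecord], min_mapq: int = 30, max_insert: int = 100
) -> tuple[list[FragmentRecord], Counter]:
    """Keep *effective fragments*: mapq >= ``min_mapq`` (uniquely mapped)
    and insert size <= ``max_insert``. Order is preserved; the second
    return value counts the fragments dropped by each reason (a fragment
    failing both counts under ``low_mapq``)."""
    kept: list[FragmentRecord] = []
    dropped: Counter = Counter()
    for fr in frags:
        if fr.mapq < min_mapq:
            dropped["low_mapq"] += 1
        elif fr.insert_size > max_insert:
            dropped["insert_too_long"] += 1
        else:
            kept.append(fr)
    return kept, dropped


def _trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def rpm_coverage(
    frags: Sequence[FragmentRecord], positions: Sequence[GenomicInterval]
) -> list[float]:
    """Coverage at each query position in RPM (fragments per million).

    value = (# effective fragments overlapping the position) × 10⁶ /
    (total effective fragments). Callers are expected to have run
    :func:`filter_fragments` first.
    """
    total = len(frags)
    if total < 1:
        raise ValueError("need at least one fragment for RPM normalization")
    # tag each fragment with its index so identical intervals stay distinct
    trees: dict[str, IntervalTree] = {}
    for i, fr in enumerate(frags):
        iv = fr.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    out = []
    for pos in positions:
        tree = trees.get(pos.chrom)
        count = len(tree.overlap(pos.start, pos.end)) if tree is not None else 0
        out.append(count * 1e6 / total)
    return out


def condition_specific_peaks(
    a_high: Sequence[GenomicInterval],
    a_low: Sequence[GenomicInterval],
    b_high: Sequence[GenomicInterval],
    b_low: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Peaks specific to each condition.

    A peak called at the stringent (high) threshold in one condition is
    specific to that condition iff it overlaps no peak called at the
    lenient (low) threshold in the other condition.
    """
    b_low_trees = _trees(b_low)
    a_low_trees = _trees(a_low)

    def specific(high: Sequence[GenomicInterval], other_low: dict[str, IntervalTree]):
        out = []
        for pk in high:
            tree = other_low.get(pk.chrom)
            if tree is None or not tree.overlap(pk.start, pk.end):
                out.append(pk)
        return out

    return specific(a_high, b_low_trees), specific(b_high, a_low_trees)


def promoter_association(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    flank: int = 1000,
) -> dict[str, list[GenomicInterval]]:
    """Associate genes with peaks overlapping their promoter window.

    The promoter is the half-open window [max(0, tss − flank), tss + flank)
    regardless of strand; a gene is associated with every peak sharing at
    least one base with it. Every gene appears in the result (possibly with
    an empty peak list).
    """
    peak_trees: dict[str, IntervalTree] = {}
    peak_lookup: dict[str, list[GenomicInterval]] = {}
    for pk in peaks:
        peak_trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, pk)
        peak_lookup.setdefault(pk.chrom, []).append(pk)
    out: dict[str, list[GenomicInterval]] = {}
    for gene in genes:
        lo, hi = max(0, gene.tss - flank), gene.tss + flank
        tree = peak_trees.get(gene.chrom)
        hits = [h.data for h in tree.overlap(lo, hi)] if tree is not None else []
        out[gene.gene] = sorted(hits)
    return out


# ---------------------------------------------------------------------------
# BED / table io (plain TSV; bit-exact round trips)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if iv.strand == "." and names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fragment_bed(path: str | Path) -> list[FragmentRecord]:
    """Fragment BED: chrom, start, end, name, mapq (score column), strand."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"fragment BED needs >= 5 columns, got: {line!r}")
            strand = f[5] if len(f) >= 6 else "."
            out.append(
                FragmentRecord(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                    name=f[3],
                    mapq=int(f[4]),
                )
            )
    return out


def write_fragment_bed(frags: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in frags:
            iv = fr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fr.name}\t{fr.mapq}\t{iv.strand}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Gene table CSV with header gene,chrom,tss,strand."""
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                GeneAnnotation(
                    gene=row["gene"], chrom=row["chrom"], tss=int(row["tss"]),
                    strand=row["strand"],
                )
            )
    return out


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "chrom", "tss", "strand"])
        for g in genes:
            w.writerow([g.gene, g.chrom, g.tss, g.strand])
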