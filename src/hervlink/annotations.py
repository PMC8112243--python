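"""Genomic feature types and annotation I/O.

Internal coordinates are 0-based half-open throughout; GTF I/O converts at
the boundary (GTF is 1-based closed), BED is read and written as-is.
Strand is stored but never used in distance computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Unstranded gap in bp between half-open intervals; 0 when overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, other.start - self.end, self.start - other.end)


@dataclass(frozen=True)
class GeneFeature:
    """A gene with optional exon structure.

    Exons must lie within the gene interval and be non-overlapping once
    sorted by start.
    """

    interval: GenomicInterval
    gene_id: str
    symbol: str = ""
    biotype: str = "other"
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            object.__setattr__(self, "biotype", "other")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"exon of {self.gene_id} on wrong chromosome")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon of {self.gene_id} outside gene interval")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", exons)


@dataclass(frozen=True)
class HervLocus:
    """One HERV proviral locus.

    ``locus_id`` follows the FAMILY_cytoband convention (e.g.
    ``ERV316A3_12q24.13``); ``family`` is the portion before the first
    underscore. ``is_coding`` and ``in_enhancer`` are annotation flags
    consumed as given, never computed here.
    """

    interval: GenomicInterval
    locus_id: str
    family: str = ""
    is_coding: bool = False
    in_enhancer: bool = False

    def __post_init__(self) -> None:
        if not self.family:
            object.__setattr__(
                self, "family", self.locus_id.split("_", 1)[0] or "unknown"
            )


def _chrom_index(features, key):
    by_chrom: dict[str, list] = {}
    for f in features:
        by_chrom.setdefault(key(f).chrom, []).append(f)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda f: (key(f).start, key(f).end))
    return by_chrom


@dataclass
class AnnotationSet:
    """Genes and HERV loci with per-chromosome start-sorted indexes."""

    genes: list[GeneFeature] = field(default_factory=list)
    hervs: list[HervLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.locus_id for h in self.hervs]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValueError(f"duplicate locus_id(s): {sorted(dupes)}")
        gids = [g.gene_id for g in self.genes]
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate gene_id in annotation")
        self._genes_by_chrom = _chrom_index(self.genes, lambda g: g.interval)
        self._hervs_by_chrom = _chrom_index(self.hervs, lambda h: h.interval)
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        self._herv_by_id = {h.locus_id: h for h in self.hervs}
        # parallel start/end arrays per chromosome for windowed queries
        self._gene_arrays = {
            c: (
                np.array([g.interval.start for g in gs], dtype=np.int64),
                np.array([g.interval.end for g in gs], dtype=np.int64),
            )
            for c, gs in self._genes_by_chrom.items()
        }

    def genes_on(self, chrom: str) -> list[GeneFeature]:
        return self._genes_by_chrom.get(chrom, [])

    def hervs_on(self, chrom: str) -> list[HervLocus]:
        return self._hervs_by_chrom.get(chrom, [])

    def gene(self, gene_id: str) -> GeneFeature:
        return self._gene_by_id[gene_id]

    def herv(self, locus_id: str) -> HervLocus:
        return self._herv_by_id[locus_id]

    def genes_in_window(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        """Genes whose interval overlaps [start, end) on chrom."""
        genes = self._genes_by_chrom.get(chrom)
        if not genes:
            return []
        starts, ends = self._gene_arrays[chrom]
        hit = (starts < end) & (ends > start)
        return [g for g, h in zip(genes, hit) if h]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(set(self._genes_by_chrom) | set(self._hervs_by_chrom))


# ---------------------------------------------------------------------------
# I/O


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(gtf_path, herv_bed_path) -> AnnotationSet:
    """Read gene/exon GTF plus HERV BED6+ into an :class:`AnnotationSet`.

    GTF 1-based closed coordinates are converted to internal 0-based
    half-open. BED column 4 is the locus_id (family parsed from its prefix);
    optional columns 7 and 8 carry is_coding / in_enhancer as 0/1.
    Malformed records are skipped with a warning naming the line number;
    duplicate locus ids are a hard error.
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[GenomicInterval]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                warnings.warn(f"{gtf_path}:{lineno}: short GTF record skipped")
                continue
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            try:
                start = int(start_s) - 1  # GTF 1-based closed -> 0-based half-open
                end = int(end_s)
                if start >= end:
                    raise ValueError
            except ValueError:
                warnings.warn(f"{gtf_path}:{lineno}: malformed coordinates skipped")
                continue
            attrs = _parse_gtf_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                warnings.warn(f"{gtf_path}:{lineno}: missing gene_id skipped")
                continue
            iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
            if feature == "gene":
                gene_rows[gene_id] = {
                    "interval": iv,
                    "symbol": attrs.get("gene_name", gene_id),
                    "biotype": attrs.get("gene_biotype", "other"),
                }
            elif feature == "exon":
                exon_rows.setdefault(gene_id, []).append(iv)

    genes = [
        GeneFeature(
            interval=row["interval"],
            gene_id=gid,
            symbol=row["symbol"],
            biotype=row["biotype"] if row["biotype"] in BIOTYPES else "other",
            exons=tuple(exon_rows.get(gid, ())),
        )
        for gid, row in gene_rows.items()
    ]

    hervs = []
    seen: set[str] = set()
    with open(herv_bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                warnings.warn(f"{herv_bed_path}:{lineno}: short BED record skipped")
                continue
            chrom, start_s, end_s, locus_id, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                if start >= end:
                    raise ValueError
            except ValueError:
                warnings.warn(f"{herv_bed_path}:{lineno}: malformed coordinates skipped")
                continue
            if locus_id in seen:
                raise ValueError(f"duplicate locus_id {locus_id!r} at {herv_bed_path}:{lineno}")
            seen.add(locus_id)
            is_coding = len(fields) > 6 and fields[6] not in ("0", "", ".")
            in_enhancer = len(fields) > 7 and fields[7] not in ("0", "", ".")
            hervs.append(
                HervLocus(
                    interval=GenomicInterval(chrom, start, end, strand if strand in "+-" else "."),
                    locus_id=locus_id,
                    is_coding=is_coding,
                    in_enhancer=in_enhancer,
                )
            )
    return AnnotationSet(genes=genes, hervs=hervs)


def write_annotation(ann: AnnotationSet, gtf_path, herv_bed_path) -> None:
    """Write genes/exons as GTF and HERV loci as BED6+2 (coding, enhancer)."""
    with open(gtf_path, "w") as fh:
        for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\thervlink\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\thervlink\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
    with open(herv_bed_path, "w") as fh:
        for h in sorted(ann.hervs, key=lambda h: (h.interval.chrom, h.interval.start)):
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.locus_id}\t0\t"
                f"{iv.strand}\t"
                f"{int(h.is_coding)}\t{int(h.in_enhancer)}\n"
            )
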