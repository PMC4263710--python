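"""Gene annotation handling: GTF I/O, annotation merging, biotype classification,
and genomic neighbor queries.

Coordinates are internally 0-based half-open; GTF I/O converts to and from the
format's 1-based inclusive convention.  Overlap and gap arithmetic is
strand-agnostic throughout: antisense gene pairs (opposite strands, overlapping
or abutting spans) are legitimate neighbors in this analysis, so strand never
enters the distance computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GeneSet",
    "NeighborPair",
    "GtfParseError",
    "SMALL_RNA_BIOTYPES",
    "read_gtf",
    "write_gtf",
    "merge_nonoverlapping",
    "classify_genes",
    "gene_gap",
    "nearest_coding_neighbor",
]

#: Ensembl small-RNA biotypes excluded from the long non-coding class.
SMALL_RNA_BIOTYPES = frozenset(
    {"tRNA", "rRNA", "snRNA", "snoRNA", "miRNA", "miscRNA"}
)

_CODING_BIOTYPES = frozenset({"protein_coding"})


class GtfParseError(ValueError):
    """Raised for malformed GTF input; the message names the offending line."""


def _norm_biotype(biotype: str) -> str:
    return biotype.replace("_", "").replace("-", "").lower()


@dataclass(frozen=True)
class GeneModel:
    """A gene-level annotation record.

    ``start``/``end`` span all exons (0-based half-open).  ``klass`` is the
    analysis class (coding / lncRNA / small_rna / other) assigned by
    :func:`classify_genes`; ``biotype`` is the source-supplied biotype string.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"
    klass: Optional[str] = None
    source: str = "ontomap"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: require start < end, got [{self.start}, {self.end})")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: exons must be non-empty")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: exon ({s}, {e}) outside gene span [{self.start}, {self.end})"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class GeneSet:
    """An ordered collection of :class:`GeneModel` with unique gene ids."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in GeneSet")
            self._genes[g.gene_id] = g
        self._coding_index_cache: Optional[dict] = None

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self._genes == other._genes

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def sorted_by_position(self) -> list[GeneModel]:
        return sorted(self._genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.sorted_by_position():
            out.setdefault(g.chrom, []).append(g)
        return out

    def of_class(self, klass: str) -> list[GeneModel]:
        return [g for g in self._genes.values() if g.klass == klass]

    def _coding_index(self) -> dict[str, tuple[list[GeneModel], list[int], list[int]]]:
        """Per-chromosome coding genes sorted by (start, gene_id), with span arrays."""
        if self._coding_index_cache is None:
            idx: dict[str, tuple[list, list, list]] = {}
            for chrom, genes in self.by_chrom().items():
                coding = [g for g in genes if g.klass == "coding"]
                if coding:
                    idx[chrom] = (
                        coding,
                        [g.start for g in coding],
                        [g.end for g in coding],
                    )
            self._coding_index_cache = idx
        return self._coding_index_cache


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> GeneSet:
    """Read a GTF file into a :class:`GeneSet`.

    One :class:`GeneModel` per ``gene_id``; the gene span is the min/max over
    its exon features.  ``gene`` feature lines contribute metadata (biotype,
    source); a gene with a ``gene`` line but no exon lines gets a single exon
    covering its span.  Biotype is taken from the ``gene_biotype`` (or
    ``gene_type``) attribute, defaulting to ``"unknown"``.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"{path}: line {lineno}: invalid coordinate range {start1}..{end1}"
                )
            if strand not in ("+", "-"):
                raise GtfParseError(f"{path}: line {lineno}: invalid strand {strand!r}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id attribute")
            # 1-based inclusive -> 0-based half-open
            span = (start1 - 1, end1)
            if gene_id not in meta:
                order.append(gene_id)
                meta[gene_id] = {"chrom": chrom, "strand": strand, "source": source,
                                 "biotype": "unknown"}
            m = meta[gene_id]
            if m["chrom"] != chrom or m["strand"] != strand:
                raise GtfParseError(
                    f"{path}: line {lineno}: gene {gene_id} spans conflicting "
                    f"chromosome/strand assignments"
                )
            biotype = attributes.get("gene_biotype") or attributes.get("gene_type")
            if biotype:
                m["biotype"] = biotype
            if feature == "exon":
                exons.setdefault(gene_id, []).append(span)
            elif feature == "gene":
                m.setdefault("gene_span", span)

    genes = []
    for gid in order:
        m = meta[gid]
        ex = sorted(exons.get(gid, []))
        if not ex:
            if "gene_span" not in m:
                continue  # no positional features for this id
            ex = [m["gene_span"]]
        start = min(s for s, _ in ex)
        end = max(e for _, e in ex)
        genes.append(
            GeneModel(
                gene_id=gid, chrom=m["chrom"], strand=m["strand"],
                start=start, end=end, exons=tuple(ex),
                biotype=m["biotype"], source=m["source"],
            )
        )
    return GeneSet(genes)


def write_gtf(gs: GeneSet, path: str | Path) -> None:
    """Write a GeneSet as GTF (one ``gene`` line plus one ``exon`` line per exon).

    Inverse of :func:`read_gtf` up to coordinate-convention conversion; genes
    are emitted sorted by (chrom, start, gene_id).
    """
    with open(path, "w") as fh:
        for g in gs.sorted_by_position():
            attrs = f'gene_id "{g.gene_id}";'
            if g.biotype != "unknown":
                attrs += f' gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{g.source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\t{g.source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


# ---------------------------------------------------------------------------
# Merging and classification


def merge_nonoverlapping(
    primary: GeneSet,
    secondary: GeneSet,
    primary_tag: str = "primary",
    secondary_tag: str = "secondary",
) -> GeneSet:
    """Merge two annotation sets, keeping secondary genes that overlap no primary gene.

    Overlap is span-based, strand-agnostic, and half-open (abutting genes do
    not overlap).  Every gene in the result is tagged with its source.
    """
    trees: dict[str, IntervalTree] = {}
    merged: list[GeneModel] = []
    for g in primary:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        merged.append(replace(g, source=primary_tag))
    for g in secondary:
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlaps(g.start, g.end):
            continue
        if g.gene_id in primary:
            raise ValueError(
                f"gene_id {g.gene_id!r} present in both annotation sources"
            )
        merged.append(replace(g, source=secondary_tag))
    return GeneSet(merged)


def classify_genes(
    gs: GeneSet,
    small_rna_biotypes: frozenset[str] | set[str] = SMALL_RNA_BIOTYPES,
    coding_biotypes: frozenset[str] | set[str] = _CODING_BIOTYPES,
) -> GeneSet:
    """Assign the analysis class (coding / small_rna / lncRNA) from biotypes.

    Genes without biotype information (e.g. secondary-source noncoding models)
    fall through to lncRNA, as do all remaining non-coding biotypes
    (antisense, lincRNA, processed_transcript, ...).  Biotype matching is
    case- and punctuation-insensitive ("misc_RNA" matches "miscRNA").
    """
    small = {_norm_biotype(b) for b in small_rna_biotypes}
    coding = {_norm_biotype(b) for b in coding_biotypes}
    out = []
    for g in gs:
        b = _norm_biotype(g.biotype)
        if b in coding:
            klass = "coding"
        elif b in small:
            klass = "small_rna"
        else:
            klass = "lncRNA"
        out.append(replace(g, klass=klass))
    return GeneSet(out)


# ---------------------------------------------------------------------------
# Distances and neighbors


def gene_gap(a: GeneModel, b: GeneModel) -> Optional[int]:
    """Bases strictly between two gene spans; 0 if they overlap or abut.

    Returns None for genes on different chromosomes.  Strand-agnostic.
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start - b.end, b.start - a.end, 0)


@dataclass(frozen=True)
class NeighborPair:
    """An anchor gene paired with its nearest coding neighbor.

    For PC-NC pairs the anchor (``id_a``) is the lncRNA.  ``gap_bp`` is None
    for random pairs, where genomic distance is not meaningful.
    """

    id_a: str
    id_b: str
    pair_class: str  # PC-PC, PC-NC, or random-PC
    gap_bp: Optional[int]
    tier: str = "all"  # all | hi
    r: Optional[float] = None


def nearest_coding_neighbor(g: GeneModel, gs: GeneSet) -> Optional[NeighborPair]:
    """The coding gene on ``g``'s chromosome minimizing :func:`gene_gap`.

    The gene itself is excluded from the candidate set.  Ties are broken by
    smaller start coordinate, then lexicographic gene_id.  Returns None when
    the chromosome has no other coding gene.
    """
    idx = gs._coding_index().get(g.chrom)
    if idx is None:
        return None
    coding, starts, ends = idx
    best: Optional[tuple[int, int, str]] = None
    best_gene: Optional[GeneModel] = None
    for cand, cs, ce in zip(coding, starts, ends):
        if cand.gene_id == g.gene_id:
            continue
        gap = max(g.start - ce, cs - g.end, 0)
        key = (gap, cs, cand.gene_id)
        if best is None or key < best:
            best, best_gene = key, cand
    if best_gene is None:
        return None
    pair_class = "PC-PC" if g.klass == "coding" else "PC-NC"
    return NeighborPair(
        id_a=g.gene_id, id_b=best_gene.gene_id, pair_class=pair_class,
        gap_bp=best[0], tier="all", r=None,
    )
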