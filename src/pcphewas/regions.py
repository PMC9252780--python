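"""Gene annotations and padded genomic intervals.

Gene regions follow the Ensembl convention: coordinates are 1-based and
inclusive on both ends.  Only protein-coding and lincRNA genes are analyzed;
the padded interval of a protein-coding gene is extended strand-aware (the
upstream padding is applied on the transcription-start side), while lincRNA
intervals are used as annotated, without padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

ALLOWED_BIOTYPES = frozenset({"protein_coding", "lincRNA"})

#: Default padding for protein-coding genes (bp): 1.5 kb upstream, 1 kb
#: downstream of the annotated gene boundaries.
DEFAULT_UPSTREAM_BP = 1500
DEFAULT_DOWNSTREAM_BP = 1000

_TSV_COLUMNS = ("gene_id", "symbol", "chrom", "start", "end", "strand", "biotype")


class AnnotationError(ValueError):
    """Raised when an annotation file cannot be parsed."""


@dataclass(frozen=True)
class GeneRegion:
    """An annotated gene interval (1-based, inclusive)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.biotype not in ALLOWED_BIOTYPES:
            raise ValueError(f"{self.gene_id}: unsupported biotype {self.biotype!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"interval start ({self.start}) > end ({self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def pad_region(
    gene: GeneRegion,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
) -> GenomicInterval:
    """Compute the padded interval from which a gene's variants are drawn.

    Protein-coding genes are extended by ``upstream_bp`` on the 5' side and
    ``downstream_bp`` on the 3' side, where the 5' side depends on strand.
    lincRNA genes are returned unpadded.  The start is clamped at position 1.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("padding must be non-negative")
    if gene.biotype == "lincRNA":
        return GenomicInterval(gene.chrom, gene.start, gene.end)
    if gene.strand == "+":
        start = gene.start - upstream_bp
        end = gene.end + downstream_bp
    else:
        start = gene.start - downstream_bp
        end = gene.end + upstream_bp
    return GenomicInterval(gene.chrom, max(start, 1), end)


def _load_tsv(path: Path) -> list[GeneRegion]:
    genes: list[GeneRegion] = []
    skipped = 0
    with open(path) as fh:
        header = fh.readline()
        if not header:
            logger.warning("empty annotation file: %s", path)
            return genes
        cols = header.rstrip("\n").split("\t")
        if tuple(cols) != _TSV_COLUMNS:
            raise AnnotationError(
                f"{path}: expected header {list(_TSV_COLUMNS)}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise AnnotationError(
                    f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            gene_id, symbol, chrom, start, end, strand, biotype = fields
            if biotype not in ALLOWED_BIOTYPES:
                skipped += 1
                continue
            try:
                genes.append(
                    GeneRegion(gene_id, symbol, chrom, int(start), int(end),
                               strand, biotype)
                )
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        logger.info("skipped %d gene(s) with unsupported biotype", skipped)
    if not genes:
        logger.warning("no analyzable genes found in %s", path)
    return genes


def _load_gff3(path: Path) -> list[GeneRegion]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRegion] = []
    skipped = 0
    for feat in db.features_of_type("gene"):
        biotype = (feat.attributes.get("biotype")
                   or feat.attributes.get("gene_biotype") or [""])[0]
        if biotype not in ALLOWED_BIOTYPES:
            skipped += 1
            continue
        if feat.strand not in {"+", "-"}:
            raise AnnotationError(
                f"{path}: gene {feat.id}: unknown strand {feat.strand!r}"
            )
        gene_id = (feat.attributes.get("ID") or [feat.id])[0]
        # GFF3 ID attributes are often prefixed, e.g. "gene:ENSG...".
        if ":" in gene_id:
            gene_id = gene_id.split(":", 1)[1]
        symbol = (feat.attributes.get("Name") or [gene_id])[0]
        genes.append(
            GeneRegion(gene_id, symbol, feat.seqid, feat.start, feat.end,
                       feat.strand, biotype)
        )
    if skipped:
        logger.info("skipped %d gene(s) with unsupported biotype", skipped)
    if not genes:
        logger.warning("no analyzable genes found in %s", path)
    return genes


def load_gene_annotations(path: str | Path, format: str | None = None) -> list[GeneRegion]:
    """Load gene annotations from a GFF3 file or a 7-column TSV.

    Genes whose biotype is not protein_coding or lincRNA are skipped (the
    skip count is logged).  Returns one :class:`GeneRegion` per kept record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        return _load_gff3(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown annotation format: {format!r}")
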