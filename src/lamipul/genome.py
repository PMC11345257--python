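"""Ordered, stranded gene model of an annotated (draft) genome.

All window-based analyses in this package (PUL calling, neighbourhood
inspection, dispersion measurement) operate on *ORF ranks*: the 0-based
ordinal of a gene along its contig, sorted by ascending start coordinate.
Coordinates are 1-based inclusive throughout (GenBank/GFF3 convention);
the single BED-style conversion lives in :func:`to_bed_interval`.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import FormatError, UnknownGeneError, ValidationError

STRANDS = frozenset({"+", "-"})

#: TSV column order used by :meth:`GenomeAnnotation.to_tsv` / :meth:`from_tsv`.
GENE_TABLE_COLUMNS = ("gene_id", "contig", "start", "end", "strand", "protein_id", "product")


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span to a BED 0-based half-open interval."""
    return start - 1, end


@dataclass
class GeneRecord:
    """One gene/CDS on a contig.

    ``rank`` is assigned by :class:`GenomeAnnotation` after sorting the
    contig's genes by (start, end, gene_id); it is the unit of all window
    distances in this package.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    product: str = ""
    rank: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: end {self.end} < start {self.start}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id!r}: start {self.start} < 1")
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand {self.strand!r} not in {{+,-}}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


class GenomeAnnotation:
    """Ordered map contig_id -> list of :class:`GeneRecord`, ranked by start.

    Parameters
    ----------
    genes
        Gene records in any order; ranks are (re)assigned here.
    organism
        Free-text organism / assembly name.
    circular
        Per-contig circularity; contigs absent from the mapping are linear
        (NCBI draft scaffolds are linear).
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        organism: str = "",
        circular: Mapping[str, bool] | None = None,
    ) -> None:
        self.organism = organism
        self.contigs: dict[str, list[GeneRecord]] = {}
        for g in genes:
            self.contigs.setdefault(g.contig_id, []).append(g)
        self._index: dict[str, GeneRecord] = {}
        self._protein_index: dict[str, GeneRecord] = {}
        for contig_genes in self.contigs.values():
            contig_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(contig_genes):
                g.rank = rank
                if g.gene_id in self._index:
                    raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
                self._index[g.gene_id] = g
                if g.protein_id:
                    self._protein_index.setdefault(g.protein_id, g)
        self.circular: dict[str, bool] = {c: False for c in self.contigs}
        if circular:
            for c, flag in circular.items():
                self.circular[c] = bool(flag)

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def genes(self) -> Iterator[GeneRecord]:
        """All genes, contig by contig in insertion order, rank order within."""
        for contig_genes in self.contigs.values():
            yield from contig_genes

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise UnknownGeneError(f"unknown gene_id {gene_id!r}") from None

    def find(self, identifier: str) -> GeneRecord:
        """Look up by gene_id, falling back to protein_id."""
        if identifier in self._index:
            return self._index[identifier]
        if identifier in self._protein_index:
            return self._protein_index[identifier]
        raise UnknownGeneError(f"unknown gene/protein id {identifier!r}")

    # -- neighbourhoods --------------------------------------------------

    def neighborhood(self, anchor: str, up: int, down: int) -> list[GeneRecord]:
        """Genes within ``up`` ranks left and ``down`` ranks right of the anchor.

        "Upstream/downstream" is contig rank order (strand-symmetric), not
        the anchor's reading direction. Linear contigs truncate at the ends;
        circular contigs wrap across the origin (each gene returned once).
        """
        if up < 0 or down < 0:
            raise ValueError("up and down must be >= 0")
        g = self.get(anchor)
        contig_genes = self.contigs[g.contig_id]
        n = len(contig_genes)
        if self.circular.get(g.contig_id, False):
            seen: set[int] = set()
            out = []
            for offset in range(-up, down + 1):
                i = (g.rank + offset) % n
                if i not in seen:
                    seen.add(i)
                    out.append(contig_genes[i])
            return out
        lo = max(0, g.rank - up)
        hi = min(n - 1, g.rank + down)
        return contig_genes[lo : hi + 1]

    def rank_distance(self, gene_a: str, gene_b: str) -> int | None:
        """ORF-rank distance between two genes; ``None`` across contigs.

        On circular contigs the shorter way around is used.
        """
        a, b = self.get(gene_a), self.get(gene_b)
        if a.contig_id != b.contig_id:
            return None
        d = abs(a.rank - b.rank)
        if self.circular.get(a.contig_id, False):
            n = len(self.contigs[a.contig_id])
            d = min(d, n - d)
        return d

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_gff3(cls, path: str | Path, organism: str = "",
                  circular: Mapping[str, bool] | None = None) -> "GenomeAnnotation":
        import gffutils

        try:
            with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
                db = gffutils.create_db(
                    str(path), dbfn=tmp.name, force=True, keep_order=True,
                    merge_strategy="create_unique",
                )
                genes = []
                cds_with_gene_parent: set[str] = set()
                for feat in db.features_of_type("CDS"):
                    for parent in db.parents(feat, featuretype="gene"):
                        cds_with_gene_parent.add(feat.id)
                records: list = []
                for feat in db.features_of_type("gene"):
                    protein_id = _attr(feat, "protein_id")
                    product = _attr(feat, "product") or ""
                    for cds in db.children(feat, featuretype="CDS"):
                        protein_id = _attr(cds, "protein_id") or protein_id
                        product = _attr(cds, "product") or product
                    records.append((feat, protein_id, product))
                for feat in db.features_of_type("CDS"):
                    if feat.id in cds_with_gene_parent:
                        continue
                    records.append((feat, _attr(feat, "protein_id"), _attr(feat, "product") or ""))
                for feat, protein_id, product in records:
                    gene_id = _attr(feat, "locus_tag") or _attr(feat, "ID") or feat.id
                    genes.append(GeneRecord(
                        gene_id=gene_id, contig_id=feat.seqid,
                        start=feat.start, end=feat.end, strand=feat.strand,
                        protein_id=protein_id, product=product or _attr(feat, "product") or "",
                    ))
        except ValidationError:
            raise
        except Exception as exc:  # gffutils raises assorted parse errors
            raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
        if not genes:
            raise FormatError(f"no gene/CDS features found in {path}")
        return cls(genes, organism=organism, circular=circular)

    @classmethod
    def from_genbank(cls, path: str | Path,
                     circular: Mapping[str, bool] | None = None) -> "GenomeAnnotation":
        from Bio import SeqIO

        genes: list[GeneRecord] = []
        organism = ""
        detected_circular: dict[str, bool] = {}
        try:
            for record in SeqIO.parse(str(path), "genbank"):
                organism = organism or record.annotations.get("organism", "")
                if record.annotations.get("topology") == "circular":
                    detected_circular[record.id] = True
                counter = 0
                for feat in record.features:
                    if feat.type != "CDS":
                        continue
                    counter += 1
                    q = feat.qualifiers
                    gene_id = (q.get("locus_tag") or q.get("gene")
                               or q.get("protein_id") or [f"{record.id}_CDS{counter}"])[0]
                    genes.append(GeneRecord(
                        gene_id=gene_id,
                        contig_id=record.id,
                        # outer span of (possibly joined) location, 1-based inclusive
                        start=int(feat.location.start) + 1,
                        end=int(feat.location.end),
                        strand="-" if feat.location.strand == -1 else "+",
                        protein_id=(q.get("protein_id") or [None])[0],
                        product=(q.get("product") or [""])[0],
                    ))
        except ValidationError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot parse GenBank {path}: {exc}") from exc
        if not genes:
            raise FormatError(f"no CDS features found in {path}")
        if circular:
            detected_circular.update(circular)
        return cls(genes, organism=organism, circular=detected_circular)

    @classmethod
    def from_tsv(cls, path: str | Path, organism: str = "",
                 circular: Mapping[str, bool] | None = None) -> "GenomeAnnotation":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except Exception as exc:
            raise FormatError(f"cannot parse gene table {path}: {exc}") from exc
        required = {"gene_id", "contig", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        genes = []
        for row in df.itertuples(index=False):
            genes.append(GeneRecord(
                gene_id=row.gene_id, contig_id=row.contig,
                start=int(row.start), end=int(row.end), strand=row.strand,
                protein_id=(getattr(row, "protein_id", None) or None)
                if pd.notna(getattr(row, "protein_id", None)) else None,
                product=getattr(row, "product", "")
                if pd.notna(getattr(row, "product", "")) else "",
            ))
        return cls(genes, organism=organism, circular=circular)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.contig_id, g.start, g.end, g.strand, g.protein_id or "", g.product)
            for g in self.genes()
        ]
        return pd.DataFrame(rows, columns=list(GENE_TABLE_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_gff3(self, path: str | Path) -> None:
        """Serialize as a minimal GFF3 gene table (gene features only)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes():
                attrs = [f"ID={g.gene_id}", f"locus_tag={g.gene_id}"]
                if g.protein_id:
                    attrs.append(f"protein_id={g.protein_id}")
                if g.product:
                    attrs.append(f"product={g.product}")
                fh.write(
                    f"{g.contig_id}\tlamipul\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    + ";".join(attrs) + "\n"
                )


def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def load_genome(path: str | Path, format: str | None = None,
                circular: Mapping[str, bool] | None = None) -> GenomeAnnotation:
    """Load an annotation file, auto-detecting GFF3/GenBank/TSV by suffix."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".gff": "gff3", ".gff3": "gff3",
            ".gb": "genbank", ".gbk": "genbank", ".gbff": "genbank",
            ".tsv": "tsv", ".txt": "tsv",
        }.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")
    if format == "gff3":
        return GenomeAnnotation.from_gff3(path, circular=circular)
    if format == "genbank":
        return GenomeAnnotation.from_genbank(path, circular=circular)
    if format == "tsv":
        return GenomeAnnotation.from_tsv(path, circular=circular)
    raise FormatError(f"unknown annotation format {format!r}")
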