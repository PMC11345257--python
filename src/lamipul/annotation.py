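"""Functional labels for proteins from externally produced hit tables.

Consumes dbCAN-overview-like domain-hit tables (the HMM/BLAST searches
themselves are upstream tools, not run here) and produces:

* consensus CAZyme calls — a family is accepted when at least ``min_tools``
  of the declared search tools agree (default 2 of 3, the dbCAN3 rule);
* SusC/SusD transporter classes — a *specific* hit on the TIGR04056 motif
  distinguishes sugar-transporting SusC proteins from receptors with only a
  superfamily-level hit;
* SusC/D tandem-pair detection on the gene model (the canonical Bacteroidota
  arrangement: consecutive genes, same strand, susD immediately downstream
  of susC in reading direction);
* motif scanning and GH16_3 laminarinase domain-architecture classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, FormatError, ValidationError
from .genome import GeneRecord, GenomeAnnotation

logger = logging.getLogger(__name__)

HIT_CLASSES = frozenset({"specific", "superfamily"})

#: Default label of the sugar-transporting SusC motif (specific CDD hit).
SUSC_MOTIF_LABEL = "TIGR04056"

#: Default labels accepted as evidence for SusD-family lipoproteins.
SUSD_LABELS = frozenset({"SusD", "PF07980", "PF12741", "PF12771", "PF14322"})

#: CAZy family/subfamily labels, e.g. GH16, GH16_3, CBM6.
CAZY_LABEL_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")

#: GH16_3 finger/active-site motifs used in laminarinase classification.
MOTIF_GALACTOSIDASE_FINGER1 = "WKLCTYNNAWSQ"
MOTIF_LAMINARINASE_FINGER3 = "GGTWPALWALGANFDEVGWP"
MOTIF_WPA = "WPA"


@dataclass(frozen=True)
class DomainHit:
    """One hit of one search tool on one protein."""

    protein_id: str
    tool: str
    label: str
    hit_class: str = "specific"
    start: int | None = None
    end: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.hit_class not in HIT_CLASSES:
            raise ValidationError(
                f"{self.protein_id}: hit_class {self.hit_class!r} not in {sorted(HIT_CLASSES)}"
            )
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValidationError(f"{self.protein_id}: hit start > end")


@dataclass(frozen=True)
class CazymeCall:
    protein_id: str
    family: str
    subfamily: str = ""
    support: int = 0


@dataclass(frozen=True)
class SusCall:
    protein_id: str
    sus_class: str  # susC_specific | susC_superfamily | susD
    evidence: tuple[DomainHit, ...] = ()


@dataclass
class DomainArchitecture:
    """Ordered domain layout of one protein (1-based AA coordinates)."""

    protein_id: str
    length: int
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d[1], d[2]))
        for name, start, end in self.domains:
            if not (1 <= start <= end <= self.length):
                raise ValidationError(
                    f"{self.protein_id}: domain {name} span {start}-{end} "
                    f"outside [1, {self.length}]"
                )

    def names(self) -> set[str]:
        return {name for name, _, _ in self.domains}


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    verdict: str  # canonical_large_laminarinase | non_canonical
    missing_domains: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# consensus CAZyme calling
# ---------------------------------------------------------------------------

def split_family(label: str) -> tuple[str, str] | None:
    """Split a CAZy label into (family, subfamily); None for non-CAZy labels."""
    m = CAZY_LABEL_RE.match(label)
    if m is None:
        return None
    family = f"{m.group(1)}{m.group(2)}"
    subfamily = label if m.group(3) else ""
    return family, subfamily


def consensus_cazyme(
    hits: Iterable[DomainHit],
    min_tools: int = 2,
    tool_set_size: int = 3,
    subfamily_tool: str | None = None,
    tool_set: Sequence[str] | None = None,
) -> list[CazymeCall]:
    """Vote CAZy families across search tools; keep families with enough support.

    Votes are counted per (protein, family): distinct tools reporting any
    label in that family (subfamily labels vote for their parent family).
    The subfamily string on an accepted call comes from ``subfamily_tool``
    when declared, otherwise from any subfamily-level hit.
    """
    if min_tools > tool_set_size:
        raise ConfigError(f"min_tools {min_tools} > tool_set_size {tool_set_size}")
    declared = set(tool_set) if tool_set is not None else None
    votes: dict[tuple[str, str], set[str]] = {}
    subfam: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for hit in hits:
        if declared is not None and hit.tool not in declared:
            raise ValidationError(f"hit tool {hit.tool!r} not in declared tool set")
        parsed = split_family(hit.label)
        if parsed is None:
            continue
        family, subfamily = parsed
        key = (hit.protein_id, family)
        votes.setdefault(key, set()).add(hit.tool)
        if subfamily:
            subfam.setdefault(key, set()).add((hit.tool, subfamily))
    calls = []
    for (protein_id, family), tools in sorted(votes.items()):
        support = len(tools)
        if support < min_tools:
            continue
        sub = ""
        candidates = sorted(subfam.get((protein_id, family), ()))
        if subfamily_tool is not None:
            chosen = [s for t, s in candidates if t == subfamily_tool]
            sub = chosen[0] if chosen else ""
        elif candidates:
            sub = candidates[0][1]
        calls.append(CazymeCall(protein_id, family, sub, support))
    return calls


# ---------------------------------------------------------------------------
# SusC / SusD classification and tandem pairing
# ---------------------------------------------------------------------------

def classify_sus(
    hits: Iterable[DomainHit],
    susc_motif_label: str = SUSC_MOTIF_LABEL,
    susd_labels: frozenset[str] | set[str] = SUSD_LABELS,
) -> list[SusCall]:
    """Classify proteins as susC_specific / susC_superfamily / susD.

    A protein with both SusC-motif and SusD evidence is a conflict: it is
    logged and excluded (cannot take part in tandem pairing).
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_protein.setdefault(hit.protein_id, []).append(hit)
    calls = []
    for protein_id in sorted(by_protein):
        phits = by_protein[protein_id]
        susc_hits = tuple(h for h in phits if h.label == susc_motif_label)
        susd_hits = tuple(h for h in phits if h.label in susd_labels)
        if susc_hits and susd_hits:
            logger.warning(
                "protein %s carries both SusC-motif and SusD evidence; "
                "excluded from classification", protein_id
            )
            continue
        if susc_hits:
            if any(h.hit_class == "specific" for h in susc_hits):
                calls.append(SusCall(protein_id, "susC_specific", susc_hits))
            else:
                calls.append(SusCall(protein_id, "susC_superfamily", susc_hits))
        elif susd_hits:
            calls.append(SusCall(protein_id, "susD", susd_hits))
    return calls


def detect_suscd_pairs(
    genome: GenomeAnnotation,
    sus: Iterable[SusCall],
    max_intervening: int = 0,
    strand_agnostic: bool = False,
) -> list[tuple[GeneRecord, GeneRecord]]:
    """Find susC/susD tandem pairs on the gene model.

    Default geometry: susD within ``max_intervening``+1 ranks downstream of
    susC *in the susC reading direction*, same strand. Genes are consumed
    greedily left-to-right by rank, so each gene joins at most one pair.
    """
    susc_genes: list[GeneRecord] = []
    susd_ranks: dict[tuple[str, int], GeneRecord] = {}
    for call in sus:
        try:
            gene = genome.find(call.protein_id)
        except KeyError:
            continue
        if call.sus_class.startswith("susC"):
            susc_genes.append(gene)
        elif call.sus_class == "susD":
            susd_ranks[(gene.contig_id, gene.rank)] = gene
    susc_genes.sort(key=lambda g: (g.contig_id, g.rank))
    used: set[str] = set()
    pairs = []
    for susc in susc_genes:
        if susc.gene_id in used:
            continue
        step = 1 if susc.strand == "+" else -1
        for gap in range(1, max_intervening + 2):
            susd = susd_ranks.get((susc.contig_id, susc.rank + step * gap))
            if susd is None or susd.gene_id in used:
                continue
            if not strand_agnostic and susd.strand != susc.strand:
                continue
            pairs.append((susc, susd))
            used.add(susc.gene_id)
            used.add(susd.gene_id)
            break
    return pairs


# ---------------------------------------------------------------------------
# motif scanning and GH16_3 architecture
# ---------------------------------------------------------------------------

def scan_motif(
    sequence: str, motif: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """All matches of ``motif`` in ``sequence`` with <= max_mismatch substitutions.

    Positions are 1-based AA coordinates. An ``X`` in the sequence never
    counts as matching any motif character. A motif longer than the
    sequence yields no matches (not an error).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    matches = []
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        mismatches = 0
        for s, q in zip(window, motif):
            if s == "X" or s != q:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            matches.append((i + 1, window))
    return matches


#: Domains that must all be present for the canonical large laminarinase.
GH16_REQUIRED_DOMAINS = (
    "signal_peptide",
    "PKD",
    "laminarin_binding",
    "GH16_cat_N",
    "inserted_DUF",
    "GH16_cat_C",
    "WPA_site",
)

#: Structural domains checked for ordering/overlap (WPA_site is a point
#: feature inside the catalytic domain and is exempt).
_GH16_STRUCTURAL = tuple(d for d in GH16_REQUIRED_DOMAINS if d != "WPA_site")


def classify_gh16_architecture(
    arch: DomainArchitecture,
    length_window: tuple[int, int] = (687, 705),
) -> ArchitectureCall:
    """Classify a GH16_3 architecture as canonical large laminarinase or not.

    Canonical requires every domain in :data:`GH16_REQUIRED_DOMAINS`: sec
    signal peptide, PKD beta-sandwich, laminarin-binding domain, the GH16
    catalytic domain split by an inserted domain of unknown function, and
    the WPA active-site motif. A protein length outside ``length_window``
    only raises a flag; it does not demote the class by itself.
    """
    structural = [d for d in arch.domains if d[0] in _GH16_STRUCTURAL]
    for (n1, s1, e1), (n2, s2, e2) in zip(structural, structural[1:]):
        if s2 <= e1:
            raise ValidationError(
                f"{arch.protein_id}: overlapping mandatory domains {n1} and {n2}"
            )
    present = arch.names()
    missing = tuple(d for d in GH16_REQUIRED_DOMAINS if d not in present)
    flags = []
    lo, hi = length_window
    if not (lo <= arch.length <= hi):
        flags.append(f"length_outside_{lo}_{hi}")
    verdict = "canonical_large_laminarinase" if not missing else "non_canonical"
    return ArchitectureCall(arch.protein_id, verdict, missing, tuple(flags))


def architecture_from_hits(
    protein_id: str,
    length: int,
    domain_hits: Iterable[DomainHit],
    sequence: str | None = None,
) -> DomainArchitecture:
    """Build a :class:`DomainArchitecture` from domain-table hits.

    When the WPA active site is absent from the table but a sequence is
    given, it is derived by exact-motif scanning within the catalytic span.
    """
    domains = [
        (h.label, h.start, h.end)
        for h in domain_hits
        if h.protein_id == protein_id and h.start is not None and h.end is not None
    ]
    names = {d[0] for d in domains}
    if "WPA_site" not in names and sequence is not None:
        cat_spans = [(s, e) for n, s, e in domains if n in ("GH16_cat_N", "GH16_cat_C")]
        for start, _ in scan_motif(sequence, MOTIF_WPA, 0):
            end = start + len(MOTIF_WPA) - 1
            if not cat_spans or any(s <= start and end <= e for s, e in cat_spans):
                domains.append(("WPA_site", start, end))
                break
    return DomainArchitecture(protein_id, length, domains)


# ---------------------------------------------------------------------------
# hit-table I/O (dbCAN-overview-like TSV dialect)
# ---------------------------------------------------------------------------

HIT_TABLE_COLUMNS = ("protein_id", "tool", "label", "hit_class", "start", "end", "score")


def read_hit_table(path: str | Path) -> list[DomainHit]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse hit table {path}: {exc}") from exc
    missing = {"protein_id", "tool", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(DomainHit(
            protein_id=row.protein_id, tool=row.tool, label=row.label,
            hit_class=getattr(row, "hit_class", None) or "specific",
            start=int(row.start) if _has(row, "start") else None,
            end=int(row.end) if _has(row, "end") else None,
            score=float(row.score) if _has(row, "score") else None,
        ))
    return hits


def _has(row, attr: str) -> bool:
    val = getattr(row, attr, None)
    return val is not None and not pd.isna(val) and val != ""


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    rows = [
        (h.protein_id, h.tool, h.label, h.hit_class,
         "" if h.start is None else h.start,
         "" if h.end is None else h.end,
         "" if h.score is None else h.score)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=list(HIT_TABLE_COLUMNS))


def cazyme_calls_to_frame(calls: Iterable[CazymeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.protein_id, c.family, c.subfamily, c.support) for c in calls],
        columns=["protein_id", "family", "subfamily", "support"],
    )


def sus_calls_to_frame(calls: Iterable[SusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.protein_id, c.sus_class, len(c.evidence)) for c in calls],
        columns=["protein_id", "sus_class", "n_evidence"],
    )
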