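"""Windowed polysaccharide-utilization-locus (PUL) calling and dispersion.

The operational PUL definition: a susC/susD tandem pair plus at least one
CAZyme gene within ``reach`` ORF ranks. Around an anchor gene, a window of
``up`` ORFs to the left and ``down`` ORFs to the right (default 7/7) is
inspected; the verdict is PUL iff a complete pair lies inside that window
and a CAZyme (the anchor itself counts, when it carries a CAZyme call) is
within reach of the nearer pair member (default) or of the anchor
(``mode="anchor"``).

Dispersion of a pathway gene set is judged on ORF ranks: clustered iff all
genes share a contig and fit inside a window of ``threshold`` ORFs
(default 15 = the full 7+1+7 inspection window); otherwise dispersed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import CazymeCall
from .exceptions import ConfigError
from .genome import GeneRecord, GenomeAnnotation, to_bed_interval

PAIR_MODE = "pair"
ANCHOR_MODE = "anchor"


@dataclass
class PulCall:
    """Verdict of the windowed PUL rule at one anchor gene."""

    anchor_gene_id: str
    window: list[str] = field(default_factory=list)
    pair_found: bool = False
    pair_genes: tuple[str, str] | None = None  # (susC, susD)
    cazymes_in_reach: list[str] = field(default_factory=list)
    verdict: str = "no_PUL"
    span_bp: tuple[int, int] | None = None
    contig_id: str = ""


@dataclass
class DispersionReport:
    gene_set: list[str]
    pairwise_rank_distances: np.ndarray
    min_enclosing_window: int | None
    verdict: str  # clustered | dispersed
    threshold: int


def _cazyme_gene_ids(genome: GenomeAnnotation,
                     cazyme_calls: Iterable[CazymeCall]) -> set[str]:
    ids = set()
    for call in cazyme_calls:
        try:
            ids.add(genome.find(call.protein_id).gene_id)
        except KeyError:
            continue
    return ids


def _resolve_pairs(genome: GenomeAnnotation,
                   sus_pairs: Iterable) -> list[tuple[GeneRecord, GeneRecord]]:
    resolved = []
    for susc, susd in sus_pairs:
        if not isinstance(susc, GeneRecord):
            susc = genome.find(susc)
        if not isinstance(susd, GeneRecord):
            susd = genome.find(susd)
        resolved.append((susc, susd))
    return resolved


def _rank_dist(genome: GenomeAnnotation, a: GeneRecord, b: GeneRecord) -> int:
    d = abs(a.rank - b.rank)
    if genome.circular.get(a.contig_id, False):
        n = len(genome.contigs[a.contig_id])
        d = min(d, n - d)
    return d


def call_pul_at_anchor(
    genome: GenomeAnnotation,
    cazyme_calls: Iterable[CazymeCall],
    sus_pairs: Iterable,
    anchor: str,
    up: int = 7,
    down: int = 7,
    reach: int = 8,
    mode: str = PAIR_MODE,
) -> PulCall:
    """Apply the windowed PUL rule at one anchor gene.

    ``sus_pairs`` are (susC, susD) tuples of :class:`GeneRecord` or ids, as
    produced by :func:`lamipul.annotation.detect_suscd_pairs`.
    """
    if mode not in (PAIR_MODE, ANCHOR_MODE):
        raise ConfigError(f"unknown PUL mode {mode!r}")
    anchor_gene = genome.get(anchor)
    window = genome.neighborhood(anchor, up, down)
    window_ids = [g.gene_id for g in window]
    window_set = set(window_ids)
    cazy_ids = _cazyme_gene_ids(genome, cazyme_calls)

    call = PulCall(anchor_gene_id=anchor, window=window_ids,
                   contig_id=anchor_gene.contig_id)
    candidate_pairs = [
        (susc, susd)
        for susc, susd in _resolve_pairs(genome, sus_pairs)
        if susc.gene_id in window_set and susd.gene_id in window_set
    ]
    if not candidate_pairs:
        return call
    call.pair_found = True
    # evaluate each in-window pair; first (by susC rank) that yields a PUL wins
    candidate_pairs.sort(key=lambda p: (p[0].contig_id, p[0].rank))
    call.pair_genes = (candidate_pairs[0][0].gene_id, candidate_pairs[0][1].gene_id)
    for susc, susd in candidate_pairs:
        in_reach = []
        for gid in sorted(cazy_ids):
            g = genome.get(gid)
            if g.contig_id != susc.contig_id:
                continue
            if mode == PAIR_MODE:
                dist = min(_rank_dist(genome, g, susc), _rank_dist(genome, g, susd))
            else:
                if g.contig_id != anchor_gene.contig_id:
                    continue
                dist = _rank_dist(genome, g, anchor_gene)
            if dist <= reach:
                in_reach.append(gid)
        if in_reach:
            call.pair_genes = (susc.gene_id, susd.gene_id)
            call.cazymes_in_reach = in_reach
            call.verdict = "PUL"
            evidence = [susc, susd, anchor_gene] + [genome.get(g) for g in in_reach]
            call.span_bp = (min(g.start for g in evidence), max(g.end for g in evidence))
            break
    return call


def genome_pul_catalog(
    genome: GenomeAnnotation,
    cazyme_calls: Iterable[CazymeCall],
    sus_pairs: Iterable,
    anchors: Sequence[str] | None = None,
    up: int = 7,
    down: int = 7,
    reach: int = 8,
    mode: str = PAIR_MODE,
) -> list[PulCall]:
    """Genome-wide PUL catalog: one call per susC/D pair, plus one per anchor.

    Pair-centred calls use the pair's susC gene as anchor (the pair is then
    trivially inside its own window, so the verdict reduces to the
    CAZyme-within-reach test). Calls with identical (contig, span, verdict)
    are deduplicated, keeping the first.
    """
    pairs = _resolve_pairs(genome, sus_pairs)
    calls = []
    for susc, _susd in sorted(pairs, key=lambda p: (p[0].contig_id, p[0].rank)):
        calls.append(call_pul_at_anchor(
            genome, cazyme_calls, pairs, susc.gene_id,
            up=up, down=down, reach=reach, mode=mode,
        ))
    for anchor in anchors or ():
        calls.append(call_pul_at_anchor(
            genome, cazyme_calls, pairs, anchor,
            up=up, down=down, reach=reach, mode=ANCHOR_MODE,
        ))
    seen: set[tuple] = set()
    out = []
    for call in calls:
        key = (call.contig_id, call.span_bp, call.verdict)
        if call.verdict == "PUL" and key in seen:
            continue
        seen.add(key)
        out.append(call)
    return out


def dispersion_summary(
    genome: GenomeAnnotation,
    gene_set: Sequence[str],
    threshold: int = 15,
) -> DispersionReport:
    """Judge whether a pathway gene set is clustered or dispersed.

    Distances are ORF-rank distances; genes on different contigs are at
    infinite distance and force the dispersed verdict.
    """
    genes = [genome.find(g) for g in gene_set]
    n = len(genes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = genome.rank_distance(genes[i].gene_id, genes[j].gene_id)
            dist[i, j] = np.inf if d is None else d
    contigs = {g.contig_id for g in genes}
    if len(contigs) > 1:
        window = None
        verdict = "dispersed"
    else:
        ranks = [g.rank for g in genes]
        window = max(ranks) - min(ranks) + 1
        verdict = "clustered" if window <= threshold else "dispersed"
    return DispersionReport(
        gene_set=[g.gene_id for g in genes],
        pairwise_rank_distances=dist,
        min_enclosing_window=window,
        verdict=verdict,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def catalog_to_frame(calls: Iterable[PulCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append((
            c.anchor_gene_id, c.contig_id, c.verdict, int(c.pair_found),
            c.pair_genes[0] if c.pair_genes else "",
            c.pair_genes[1] if c.pair_genes else "",
            ";".join(c.cazymes_in_reach),
            c.span_bp[0] if c.span_bp else "",
            c.span_bp[1] if c.span_bp else "",
        ))
    return pd.DataFrame(rows, columns=[
        "anchor_gene_id", "contig", "verdict", "pair_found",
        "susC", "susD", "cazymes_in_reach", "span_start", "span_end",
    ])


def catalog_to_json(calls: Iterable[PulCall], path: str | Path) -> None:
    payload = []
    for c in calls:
        payload.append({
            "anchor_gene_id": c.anchor_gene_id,
            "contig": c.contig_id,
            "verdict": c.verdict,
            "pair_found": c.pair_found,
            "pair_genes": list(c.pair_genes) if c.pair_genes else None,
            "cazymes_in_reach": c.cazymes_in_reach,
            "span_bp": list(c.span_bp) if c.span_bp else None,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def catalog_to_bed(calls: Iterable[PulCall], path: str | Path) -> None:
    """Write PUL spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in calls:
            if c.verdict != "PUL" or c.span_bp is None:
                continue
            bed_start, bed_end = to_bed_interval(*c.span_bp)
            fh.write(f"{c.contig_id}\t{bed_start}\t{bed_end}\tPUL_{c.anchor_gene_id}\n")
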