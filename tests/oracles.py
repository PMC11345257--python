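"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive every quantity by direct enumeration / naive
arithmetic, without reusing the package's window or scoring machinery.
"""

from __future__ import annotations

import numpy as np


def modular_window_ranks(n: int, anchor_rank: int, up: int, down: int,
                         circular: bool) -> list[int]:
    """Explicit index arithmetic for the expected neighbourhood ranks."""
    if circular:
        ranks = []
        for off in range(-up, down + 1):
            r = (anchor_rank + off) % n
            if r not in ranks:
                ranks.append(r)
        return ranks
    return [r for r in range(anchor_rank - up, anchor_rank + down + 1)
            if 0 <= r < n]


def naive_motif_positions(sequence: str, motif: str) -> list[int]:
    """1-based exact-substring positions, X never matching."""
    out = []
    m = len(motif)
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        if "X" not in window and window == motif:
            out.append(i + 1)
    return out


def pooled_t(a, b):
    """Textbook pooled two-sample t-statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def venn_regions(sets: dict) -> dict:
    """Per-item membership-table enumeration of Venn region counts."""
    names = sorted(sets)
    counts: dict[tuple, int] = {}
    for item in set().union(*sets.values()):
        key = tuple(n for n in names if item in sets[n])
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# brute-force PUL predicate
# ---------------------------------------------------------------------------

def _rank_dist(n: int, circular: bool, r1: int, r2: int) -> int:
    d = abs(r1 - r2)
    return min(d, n - d) if circular else d


def brute_force_pul_verdict(genome, cazyme_gene_ids, pairs, anchor_id,
                            up=7, down=7, reach=8, mode="pair") -> bool:
    """Direct evaluation of the PUL predicate by exhaustive scanning.

    ``pairs``: (susC GeneRecord, susD GeneRecord) tuples. True iff some
    pair lies fully inside the +-(up, down) rank window around the anchor
    and at least one CAZyme gene is within ``reach`` ranks of the nearer
    pair member (mode 'pair') or of the anchor (mode 'anchor').
    """
    anchor_gene = None
    for g in genome.genes():
        if g.gene_id == anchor_id:
            anchor_gene = g
            break
    assert anchor_gene is not None
    contig = genome.contigs[anchor_gene.contig_id]
    n = len(contig)
    circ = genome.circular.get(anchor_gene.contig_id, False)
    window_ranks = set(modular_window_ranks(n, anchor_gene.rank, up, down, circ))
    window_ids = {contig[r].gene_id for r in window_ranks}

    for susc, susd in pairs:
        if susc.gene_id not in window_ids or susd.gene_id not in window_ids:
            continue
        for g in genome.genes():
            if g.gene_id not in cazyme_gene_ids:
                continue
            if g.contig_id != susc.contig_id:
                continue
            if mode == "pair":
                dist = min(_rank_dist(n, circ, g.rank, susc.rank),
                           _rank_dist(n, circ, g.rank, susd.rank))
            else:
                dist = _rank_dist(n, circ, g.rank, anchor_gene.rank)
            if dist <= reach:
                return True
    return False


def exhaustive_tandem_pairs(genome, susc_ids, susd_ids):
    """All gene pairs satisfying the tandem predicate, by scanning every pair.

    Predicate: consecutive ranks on one contig, same strand, susD
    immediately downstream of susC in the susC reading direction.
    """
    out = []
    genes = list(genome.genes())
    for c in genes:
        if c.gene_id not in susc_ids:
            continue
        for d in genes:
            if d.gene_id not in susd_ids or d.contig_id != c.contig_id:
                continue
            if d.strand != c.strand:
                continue
            step = 1 if c.strand == "+" else -1
            if d.rank == c.rank + step:
                out.append((c.gene_id, d.gene_id))
    return out
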