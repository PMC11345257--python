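"""Synthetic inputs with ground truth for every pipeline stage.

Generators emulate the study design end-to-end without any downloads:

* annotated draft genomes (a few linear contigs, ~hundreds of genes each)
  with planted susC/susD tandem pairs + nearby CAZymes (PULs), planted
  *dispersed* pathway gene sets, and decoy arrangements (lone susC, lone
  susD, antiparallel susC/susD, single-tool CAZyme votes) that must yield
  negative calls;
* 3-replicate multi-condition LFQ matrices with log-normal base
  intensities, planted log2 effects, and left-censored (intensity-
  dependent) missingness — the missingness mechanism that motivates
  constant-0 imputation downstream;
* DAPI/substrate image pairs with non-overlapping cell blobs, a planted
  positive fraction and a substrate intensity offset (default 40 units
  above background, the positive-control phenotype);
* logistic OD600 growth curves with multiplicative noise.

Every generator is deterministic for a fixed seed, byte-for-byte through
the writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import DomainHit
from .genome import GeneRecord, GenomeAnnotation
from .imaging import DEFAULT_PIXEL_AREA_UM2, FluorImagePair
from .quantlab import GrowthSeries

#: dbCAN-style CAZyme search tools; dbcan_sub is the subfamily-capable one.
CAZYME_TOOLS = ("hmmer", "dbcan_sub", "diamond")
SUBFAMILY_TOOL = "dbcan_sub"
SUS_TOOL = "cdd"

#: (family, subfamily) pool for planted laminarin-pathway CAZymes.
CAZY_FAMILIES = (
    ("GH16", "GH16_3"), ("GH3", ""), ("GH17", ""),
    ("GH30", "GH30_1"), ("GH2", ""), ("GH5", "GH5_46"),
)


@dataclass
class GenomeSimConfig:
    n_contigs: int = 3
    genes_per_contig: int = 700
    n_planted_puls: int = 3
    n_dispersed_pathway_genes: int = 6
    min_dispersion_distance: int = 100  # ORF ranks, same contig
    n_lone_susc: int = 2
    n_lone_susd: int = 2
    n_antiparallel_pairs: int = 1
    n_weak_decoys: int = 20  # single-tool CAZyme votes (below consensus)
    feature_spacing: int = 25  # min rank distance between feature zones


@dataclass
class LfqSimConfig:
    n_proteins: int = 2000
    conditions: tuple[str, ...] = ("laminarin", "control")
    reps: int = 3
    effect_size: float = 4.0  # log2 units, applied to the first condition
    fraction_affected: float = 0.05
    noise_sd: float = 0.3  # log2 units
    base_mean: float = 25.0  # log2 LFQ scale
    base_sd: float = 2.0
    detection_limit: float = 21.0  # log2; below -> missing (left-censoring)


@dataclass
class ImagingSimConfig:
    shape: tuple[int, int] = (512, 512)
    n_cells: int = 150
    positive_fraction: float = 0.9
    intensity_offset: float = 40.0  # substrate units above background
    coverage: float = 0.8  # fraction of a positive cell covered by signal
    noise_sd: float = 2.0
    dapi_background: float = 10.0
    dapi_level: float = 180.0
    substrate_background: float = 20.0
    radius_range: tuple[int, int] = (3, 5)
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2


@dataclass
class GrowthSimConfig:
    model: str = "logistic"
    r: float = 0.09  # intrinsic rate, h^-1
    od0: float = 0.01
    od_max: float = 0.5
    noise_sd: float = 0.02  # multiplicative (log) noise
    interval_h: float = 2.0
    duration_h: float = 96.0


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    lfq: LfqSimConfig = field(default_factory=LfqSimConfig)
    imaging: ImagingSimConfig = field(default_factory=ImagingSimConfig)
    growth: GrowthSimConfig = field(default_factory=GrowthSimConfig)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(cfg: GenomeSimConfig, seed: int):
    """Generate (GenomeAnnotation, hit table, truth).

    Truth records the planted PULs (susC/susD/cazyme gene ids + bp span),
    the dispersed pathway gene set, all true-CAZyme gene ids, and the decoy
    arrangements, sufficient to score the PUL caller without any reference
    data.
    """
    rng = np.random.default_rng(seed)
    contig_ids = [f"CTG{i + 1:02d}" for i in range(cfg.n_contigs)]
    n_total = cfg.n_contigs * cfg.genes_per_contig

    # -- choose feature placements on the rank grid ----------------------
    # zone spacing: feature_spacing between any two features (keeps planted
    # PULs unambiguous), min_dispersion_distance pairwise among the
    # dispersed pathway genes on a shared contig.
    zones: list[tuple[int, int, str]] = []  # (contig_idx, center rank, kind)

    def _place(kind: str, margin: int = 8) -> tuple[int, int]:
        for _ in range(10_000):
            ci = int(rng.integers(cfg.n_contigs))
            rank = int(rng.integers(margin, cfg.genes_per_contig - margin))
            ok = True
            for c, r, k in zones:
                if c != ci:
                    continue
                need = (cfg.min_dispersion_distance
                        if kind == "dispersed" and k == "dispersed"
                        else cfg.feature_spacing)
                if abs(r - rank) < need:
                    ok = False
                    break
            if ok:
                zones.append((ci, rank, kind))
                return ci, rank
        raise RuntimeError("cannot place synthetic feature; genome too small")

    pul_sites = [_place("pul") for _ in range(cfg.n_planted_puls)]
    lone_susc_sites = [_place("decoy") for _ in range(cfg.n_lone_susc)]
    lone_susd_sites = [_place("decoy") for _ in range(cfg.n_lone_susd)]
    anti_sites = [_place("decoy") for _ in range(cfg.n_antiparallel_pairs)]
    dispersed_sites = [_place("dispersed")
                       for _ in range(cfg.n_dispersed_pathway_genes)]

    # -- lay out genes ----------------------------------------------------
    kinds: dict[tuple[int, int], tuple[str, dict]] = {}
    truth_puls = []
    for ci, rank in pul_sites:
        strand = str(rng.choice(["+", "-"]))
        step = 1 if strand == "+" else -1
        susd_rank = rank + step
        n_caz = int(rng.integers(1, 3))
        offsets = rng.choice([-3, -2, 2, 3, 4], size=n_caz, replace=False)
        caz_ranks = sorted(int(rank + o) for o in offsets)
        kinds[(ci, rank)] = ("susC", {"strand": strand, "hit_class": "specific"})
        kinds[(ci, susd_rank)] = ("susD", {"strand": strand})
        fams = [CAZY_FAMILIES[int(rng.integers(len(CAZY_FAMILIES)))]
                for _ in caz_ranks]
        for r, fam in zip(caz_ranks, fams):
            kinds[(ci, r)] = ("cazyme", {"family": fam,
                                         "votes": int(rng.integers(2, 4))})
        truth_puls.append({"contig_idx": ci, "susC_rank": rank,
                           "susD_rank": susd_rank, "cazyme_ranks": caz_ranks})
    for i, (ci, rank) in enumerate(lone_susc_sites):
        hit_class = "specific" if i % 2 == 0 else "superfamily"
        kinds[(ci, rank)] = ("susC", {"strand": str(rng.choice(["+", "-"])),
                                      "hit_class": hit_class})
    for ci, rank in lone_susd_sites:
        kinds[(ci, rank)] = ("susD", {"strand": str(rng.choice(["+", "-"]))})
    for ci, rank in anti_sites:
        kinds[(ci, rank)] = ("susC", {"strand": "+", "hit_class": "specific"})
        kinds[(ci, rank + 1)] = ("susD", {"strand": "-"})
    for ci, rank in dispersed_sites:
        fam = CAZY_FAMILIES[int(rng.integers(len(CAZY_FAMILIES)))]
        kinds[(ci, rank)] = ("cazyme", {"family": fam,
                                        "votes": int(rng.integers(2, 4))})

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    id_by_site: dict[tuple[int, int], str] = {}
    counter = 0
    for ci, contig_id in enumerate(contig_ids):
        lengths = rng.integers(300, 3001, size=cfg.genes_per_contig)
        gaps = rng.integers(20, 201, size=cfg.genes_per_contig)
        strands = rng.choice(["+", "-"], size=cfg.genes_per_contig)
        pos = 1
        for rank in range(cfg.genes_per_contig):
            counter += 1
            gene_id = f"SYN_{counter:05d}"
            protein_id = f"WP_SYN{counter:05d}.1"
            start = pos + int(gaps[rank])
            end = start + int(lengths[rank]) - 1
            pos = end
            kind, meta = kinds.get((ci, rank), ("background", {}))
            strand = meta.get("strand", str(strands[rank]))
            product = {
                "susC": "TonB-dependent transporter SusC",
                "susD": "SusC/D system substrate-binding protein SusD",
                "cazyme": "glycoside hydrolase",
                "background": "hypothetical protein",
            }[kind]
            genes.append(GeneRecord(gene_id, contig_id, start, end, strand,
                                    protein_id=protein_id, product=product))
            id_by_site[(ci, rank)] = gene_id
            if kind == "susC":
                hits.append(DomainHit(protein_id, SUS_TOOL, "TIGR04056",
                                      meta["hit_class"], 10, 100))
            elif kind == "susD":
                hits.append(DomainHit(protein_id, SUS_TOOL, "SusD",
                                      "specific", 10, 100))
            elif kind == "cazyme":
                family, subfamily = meta["family"]
                tools = list(rng.choice(CAZYME_TOOLS, size=meta["votes"],
                                        replace=False))
                for tool in sorted(tools):
                    label = subfamily if (tool == SUBFAMILY_TOOL and subfamily) \
                        else family
                    hits.append(DomainHit(protein_id, tool, label,
                                          "specific", 1, 250))

    # weak decoys: single-tool votes, below the consensus threshold
    feature_sites = set(kinds)
    background_sites = [(ci, r) for ci in range(cfg.n_contigs)
                        for r in range(cfg.genes_per_contig)
                        if (ci, r) not in feature_sites]
    pick = rng.choice(len(background_sites),
                      size=min(cfg.n_weak_decoys, len(background_sites)),
                      replace=False)
    weak_ids = []
    for i in sorted(pick):
        ci, rank = background_sites[i]
        gene_id = id_by_site[(ci, rank)]
        weak_ids.append(gene_id)
        protein_id = f"WP_SYN{int(gene_id.split('_')[1]):05d}.1"
        family, subfamily = CAZY_FAMILIES[int(rng.integers(len(CAZY_FAMILIES)))]
        tool = str(rng.choice(CAZYME_TOOLS))
        label = subfamily if (tool == SUBFAMILY_TOOL and subfamily) else family
        hits.append(DomainHit(protein_id, tool, label, "specific", 1, 250))

    genome = GenomeAnnotation(genes, organism=f"Synthetic draft (seed {seed})")
    truth = {
        "puls": [
            {
                "contig": contig_ids[p["contig_idx"]],
                "susC": id_by_site[(p["contig_idx"], p["susC_rank"])],
                "susD": id_by_site[(p["contig_idx"], p["susD_rank"])],
                "cazymes": [id_by_site[(p["contig_idx"], r)]
                            for r in p["cazyme_ranks"]],
            }
            for p in truth_puls
        ],
        "dispersed_genes": [id_by_site[s] for s in dispersed_sites],
        "true_cazyme_genes": sorted(
            id_by_site[s] for s, (k, _) in kinds.items() if k == "cazyme"
        ),
        "decoys": {
            "lone_susC": [id_by_site[s] for s in lone_susc_sites],
            "lone_susD": [id_by_site[s] for s in lone_susd_sites],
            "antiparallel_susC": [id_by_site[s] for s in anti_sites],
            "weak_cazyme_votes": weak_ids,
        },
    }
    return genome, hits, truth


# ---------------------------------------------------------------------------
# LFQ
# ---------------------------------------------------------------------------

def make_lfq(cfg: LfqSimConfig, seed: int):
    """Generate (LfqMatrix, truth).

    Base log2 intensities ~ N(base_mean, base_sd); a random
    ``fraction_affected`` of proteins get a signed ``effect_size`` shift in
    the first condition; replicate noise ~ N(0, noise_sd); log2 values
    below ``detection_limit`` are censored to missing. Raw (linear-scale)
    intensities are stored, as in a MaxQuant matrix.
    """
    from .proteomics import LfqMatrix

    rng = np.random.default_rng(seed)
    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    base = rng.normal(cfg.base_mean, cfg.base_sd, size=n)
    n_affected = int(round(cfg.fraction_affected * n))
    affected_idx = rng.choice(n, size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    effect = np.zeros(n)
    effect[affected_idx] = signs * cfg.effect_size

    columns = []
    data = []
    for ci, cond in enumerate(cfg.conditions):
        shift = effect if ci == 0 else 0.0
        for rep in range(1, cfg.reps + 1):
            log2_vals = base + shift + rng.normal(0.0, cfg.noise_sd, size=n)
            raw = np.power(2.0, log2_vals)
            raw[log2_vals < cfg.detection_limit] = np.nan
            columns.append((cond, rep))
            data.append(raw)
    frame = pd.DataFrame(
        np.column_stack(data), index=proteins,
        columns=pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"]),
    )
    truth = {
        "affected": [proteins[i] for i in sorted(affected_idx)],
        "true_difference": {
            proteins[i]: float(effect[i]) for i in sorted(affected_idx)
        },
        "effect_size": cfg.effect_size,
    }
    return LfqMatrix(frame), truth


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def make_images(cfg: ImagingSimConfig, seed: int):
    """Generate (FluorImagePair, truth).

    Non-overlapping DAPI disks; the first ``positive_fraction`` of cells
    (random order) receive substrate signal at background + offset over
    ``coverage`` of their area. Gaussian noise is added to both channels
    before clipping to the 8-bit range; noise_sd = 0 is the noiseless limit.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    r_lo, r_hi = cfg.radius_range
    min_sep = 2 * r_hi + 8  # keeps dilated objects disjoint
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    attempts = 0
    while len(centers) < cfg.n_cells and attempts < 200_000:
        attempts += 1
        row = int(rng.integers(r_hi + 5, h - r_hi - 5))
        col = int(rng.integers(r_hi + 5, w - r_hi - 5))
        if all((row - r) ** 2 + (col - c) ** 2 >= min_sep**2 for r, c in centers):
            centers.append((row, col))
            radii.append(int(rng.integers(r_lo, r_hi + 1)))
    if len(centers) < cfg.n_cells:
        raise RuntimeError("cannot place the requested number of cells")

    n_pos = int(round(cfg.positive_fraction * cfg.n_cells))
    order = rng.permutation(cfg.n_cells)
    positive = np.zeros(cfg.n_cells, dtype=bool)
    positive[order[:n_pos]] = True

    dapi = np.full((h, w), cfg.dapi_background, dtype=float)
    substrate = np.full((h, w), cfg.substrate_background, dtype=float)
    rows_grid, cols_grid = np.ogrid[:h, :w]
    cells = []
    for i, ((row, col), radius) in enumerate(zip(centers, radii)):
        disk = (rows_grid - row) ** 2 + (cols_grid - col) ** 2 <= radius**2
        dapi[disk] = cfg.dapi_level
        if positive[i]:
            rr, cc = np.nonzero(disk)
            order_px = np.argsort(cc, kind="stable")  # cover from one side
            n_cover = int(np.ceil(cfg.coverage * rr.size))
            sel = order_px[:n_cover]
            substrate[rr[sel], cc[sel]] = cfg.substrate_background + cfg.intensity_offset
        cells.append({"row": row, "col": col, "radius": radius,
                      "positive": bool(positive[i])})

    if cfg.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, cfg.noise_sd, size=dapi.shape)
        substrate = substrate + rng.normal(0.0, cfg.noise_sd, size=substrate.shape)
    dapi = np.clip(np.rint(dapi), 0, 255).astype(np.uint8)
    substrate = np.clip(np.rint(substrate), 0, 255).astype(np.uint8)

    pair = FluorImagePair(dapi, substrate, pixel_area_um2=cfg.pixel_area_um2)
    truth = {
        "cells": cells,
        "n_positive": int(positive.sum()),
        "positive_fraction_percent": 100.0 * positive.sum() / cfg.n_cells,
    }
    return pair, truth


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def make_growth(cfg: GrowthSimConfig, seed: int):
    """Generate (GrowthSeries, truth) from a logistic OD trajectory."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, cfg.duration_h + 1e-9, cfg.interval_h)
    if cfg.od_max <= cfg.od0:
        od = np.full_like(t, cfg.od0)
    else:
        a = (cfg.od_max - cfg.od0) / cfg.od0
        od = cfg.od_max / (1.0 + a * np.exp(-cfg.r * t))
    if cfg.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, cfg.noise_sd, size=od.shape))
    series = GrowthSeries(times=t, od=od)
    truth = {"r": cfg.r, "od0": cfg.od0, "od_max": cfg.od_max}
    return series, truth
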