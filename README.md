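# lamipul

Analysis toolkit for a recurring question in marine *Bacteroidota* genomics:
are the genes a strain uses to degrade a polysaccharide organized in a
polysaccharide utilization locus (PUL), or dispersed across the genome? The
motivating system is laminarin (the β-1,3-glucan storage sugar of algae)
utilization in *Maribacter*, where the enzymatic and transport machinery —
a large multi-domain GH16_3 endo-laminarinase, SusC/D transporters, ExbBD
energizers — is expressed on laminarin but *not* co-localized in PULs.

The package implements the full computational workflow around that
question, exercised end-to-end on synthetic data with ground truth:

* **Gene model & neighbourhoods** — GFF3/GenBank/TSV annotations parsed
  into rank-ordered contigs; all window logic runs on ORF ranks.
* **Consensus annotation** — CAZyme families accepted when ≥2 of 3 dbCAN-style
  search tools agree; SusC transporters split into TIGR04056-specific vs
  superfamily-only hits; susC/susD tandem-pair detection (consecutive,
  same strand, susD downstream in reading direction).
* **PUL calling** — the windowed rule: a SusC/D pair within ±7 ORFs of an
  anchor plus ≥1 CAZyme within 8 ORF ranks of the pair ⇒ PUL; plus a
  genome-wide catalog and a rank-based dispersion verdict for pathway
  gene sets.
* **Label-free differential expression** — the Perseus-style chain:
  detection (≥1 of 3 replicates), log2 transform, constant-0 imputation of
  missing values, and the SAM/Perseus moderated statistic

  t_s0 = (x̄_a − x̄_b) / (s_p·√(1/n_a + 1/n_b) + s0)

  with significance from a permutation-FDR volcano cut (defaults
  s0 = 0.15, FDR = 0.05).
* **Uptake imaging** — DAPI object detection (8-connected, ≥20 px ≙ 0.3 µm²)
  and substrate positivity (≥30 % area overlap and mean gray value ≥10
  units above slide background on the 0–255 scale).
* **Bench quantifications** — maximal specific growth rate µ from sliding
  log-linear OD600 windows, counting-grid→filter cell-density scale-up,
  Beer–Lambert β-glucosidase activity (ε = 7,500 M⁻¹cm⁻¹ at 405 nm),
  calibration curves and substrate-consumption percentages.
* **Synthetic data** — seeded generators for every input above, with
  planted PULs/effects/positives recorded as truth.

## Worked example

```python
from lamipul import *

genome, hits, truth = make_genome(GenomeSimConfig(), seed=11)
cazy  = consensus_cazyme(hits, subfamily_tool="dbcan_sub")
pairs = detect_suscd_pairs(genome, classify_sus(hits))
catalog = genome_pul_catalog(genome, cazy, pairs)
puls = [c for c in catalog if c.verdict == "PUL"]
print(len(genome), len(cazy), len(pairs), len(puls))
# 2100 genes, 10 CAZyme calls, 3 susC/D pairs, 3 PULs

print(puls[0].pair_genes, puls[0].cazymes_in_reach, puls[0].span_bp)
# ('SYN_00096', 'SYN_00097') ['SYN_00099', 'SYN_00100'] (157470, 167657)

print(dispersion_summary(genome, truth["dispersed_genes"]).verdict)
# dispersed

matrix, _ = make_lfq(LfqSimConfig(), seed=11)
res = differential_expression(matrix, "laminarin", "control", seed=11)
print(res.summary())
```

prints

```
Two-sample s0-moderated permutation test
==============================================
conditions:        laminarin vs control
proteins:          2000
replicates:        3 vs 3
s0:                0.15
FDR level:         0.05
permutations used: 20
|t| volcano cut:   2.4129 (est. FDR 0.0437)
significant:       103 (up 60, down 43)
```

The catalog recovered exactly the three planted PULs (each a susC/susD
tandem with its nearby CAZymes and the bp span of the evidence genes), the
planted pathway gene set is correctly called dispersed, and the volcano
flags ~100 of 2000 proteins at the s0/FDR settings — the planted 5 % with
|log2 effect| = 4.

The same stages are available from the shell:

```sh
lamipul simulate genome --seed 7 --outdir sim/
lamipul pulscan --genome sim/genes.tsv --hits sim/hits.tsv --outdir out/
lamipul de --matrix lfq.tsv --cond-a laminarin --cond-b control --seed 7 --out de.tsv
lamipul uptake --dapi dapi.png --substrate substrate.png --outdir out/
lamipul quant growth --series growth.tsv
```

Every stage is deterministic for a fixed seed — reruns are byte-identical.

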