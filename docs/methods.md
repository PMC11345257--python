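# Methods

This note documents the models, rules and numerical choices behind each
module, the synthetic-data conditions the package is validated under, and
what those validations do and do not show about real data.

## Gene model and windows

Genes are ranked 0..n−1 per contig by ascending start (ties broken by end,
then gene id, for determinism). All distances in the PUL logic are
ORF-rank distances, not bp. "Upstream/downstream" for window construction
means contig rank order (left/right), not the anchor's reading direction:
the inspection window is therefore strand-symmetric, while each gene's
strand is retained for the tandem-pair geometry. Coordinates are 1-based
inclusive internally (GenBank/GFF3 convention); the single conversion to
BED 0-based half-open intervals is `to_bed_interval`. Contigs are linear
unless declared circular (NCBI draft scaffolds are linear); circular
contigs wrap the window across the origin and use the shorter-way-around
rank distance.

## Consensus annotation

A CAZyme call requires agreement of at least `min_tools` (default 2) of
the declared search tools (default tool set size 3, mirroring dbCAN3's
HMM/subfamily/alignment engines). Votes are counted per family: a
subfamily label (GH16_3) votes for its family (GH16). This is the weaker
and safer reading of the two-of-three rule — requiring subfamily-level
agreement would make the vote depend on a capability only one engine has.
The subfamily string on an accepted call is taken from the single
subfamily-capable tool declared in configuration.

SusC classification keys on the TIGR04056 motif: a *specific* hit gives
`susC_specific`, superfamily-level hits only give `susC_superfamily`
(transporter annotation not firmly established, but still a SusC candidate
for pairing). SusD evidence is a configurable label list (the SusD-family
domain accessions shipped with the generator); no single diagnostic motif
exists for SusD. A protein with both SusC and SusD evidence is logged and
excluded from pairing.

Tandem pairs use the canonical *Bacteroidota* geometry: susD immediately
downstream of susC in the susC reading direction, same strand, consecutive
ranks. Options allow ≤k intervening ORFs and a strand-agnostic mode.
Pairing is greedy left-to-right by rank so each gene joins at most one
pair — a deterministic resolution of the rare ambiguous layouts.

## PUL rule

At an anchor gene, the verdict is PUL iff a complete susC/D pair lies
inside the ±(up, down) = ±7 ORF window *and* at least one CAZyme gene lies
within `reach` = 8 ORF ranks of the nearer pair member. The anchor itself
counts as a CAZyme when it carries a consensus call. The "within eight
ORFs" reach is pair-relative by default because the PUL concept is
SusC/D-centred; an anchor-relative mode is provided. The genome-wide
catalog emits one call per detected pair (pair-centred) plus one per
explicitly supplied anchor, deduplicated by (contig, span, verdict).

Dispersion of a pathway gene set is judged on ranks: clustered iff all
genes share a contig and fit in a window of ≤15 ORFs (the full 7+1+7
inspection window); genes on multiple contigs are dispersed by definition.

## Label-free differential expression

Detection: a protein is expressed in a condition when quantified (>0,
non-missing) in ≥1 of its 3 replicates. Venn/overlap region counts are
computed per membership pattern and always sum to the union cardinality.

Preparation: present intensities are log2-transformed; missing values are
imputed with the constant 0 *on the log2 scale*. Imputing a raw 0 would be
−∞ and is rejected. Raw intensities of exactly 1 collide with the imputed
constant after transform and are logged. Detection always runs on the
pre-imputation matrix, so imputation can never create "expressed" proteins.

Statistic: the SAM/Perseus moderated t,
`t_s0 = (mean(a) − mean(b)) / (sp·sqrt(1/na+1/nb) + s0)` with pooled
standard deviation sp and df = na+nb−2; s0 = 0 reduces exactly to the
classical pooled two-sample t-test (verified to 1e-10 against an
independent implementation). Raw two-sided p-values come from the Student
t distribution applied to t_s0. Zero pooled variance with s0 = 0 yields an
infinite statistic, reported with p → 0 and a warning.

Significance: a symmetric volcano cut on |t_s0|. For each candidate cut,
the estimated FDR is the median number of permutation exceedances across
group-label permutations divided by the number of observed exceedances;
the smallest (most inclusive) cut with estimated FDR ≤ the target is
chosen. With 3-vs-3 designs only C(6,3) = 20 distinct label assignments
exist, so the exhaustive set is used (with a warning) whenever it is
smaller than the requested permutation count; otherwise a seeded subsample
is drawn. The procedure is deterministic given the seed, and the
significant set is monotone non-increasing as the FDR target shrinks. A
non-positive FDR target admits no cut: permutations cannot certify zero
false discoveries, so nothing is called significant.

Directions: up iff significant and difference > 0; down iff significant
and difference < 0; otherwise ns. ("Upregulated" therefore means passing
the s0/FDR volcano with a positive difference.)

## Imaging

DAPI objects are 8-connected components above an Otsu threshold (a fixed
threshold can be supplied for exact reproducibility) with area ≥20 px; the
default pixel scale makes 20 px = 0.3 µm². Background MGV is the mean
substrate intensity outside all objects after a 2-px dilation, which
excludes halo bleed. The substrate signal mask is pixels ≥ background +
margin (default 10 gray units); an object is positive iff ≥30 % of its
area overlaps that mask *and* its own substrate MGV is ≥ background +
margin. The two criteria are enforced independently. Positivity is
monotone under uniform substrate-intensity increases and invariant under
image translation (both property-tested).

## Bench quantifications

Growth: µ is the maximum slope of ln(OD) over sliding windows of 4
consecutive points, restricted to windows with r² ≥ 0.98 (the
exponential-phase requirement); if no window is linear enough the steepest
window is returned flagged `low_r2`. A constant-OD window has slope 0 and
counts as a perfect fit. On a noiseless logistic curve this estimator is
biased low by the saturation factor (1 − N/K) — a few percent with the
default generator geometry — and sample noise biases the max upward; the
two effects roughly cancel, and recovery is within 5 % of the intrinsic
rate in expectation (validated over 100 seeds).

Cell density = mean(count per grid) × (filter area / grid area) / volume,
with QC flags below 30 grids or ≤280 total cells. Beer–Lambert activity:
dA/dt / (ε·path) × assay volume, in nmol s⁻¹ per µg protein, with
ε = 7,500 M⁻¹cm⁻¹ as the nitrophenol default. Calibration curves are
ordinary least squares with extrapolation flagging. Consumption percent is
100·(initial − final)/initial with out-of-range finals logged, not
rejected.

## Synthetic-data conditions

The generators define the validation conditions:

* **Genomes**: 3 linear contigs × 700 genes (≈2,100 ORFs, a typical
  *Flavobacteriaceae* draft), gene lengths 300–3,000 bp, gaps 20–200 bp,
  random strands. 3 planted PULs (susC/susD tandem + 1–2 CAZymes within 4
  ranks), 6 dispersed pathway CAZymes pairwise ≥100 ranks apart, decoys
  (lone susC — alternately specific and superfamily —, lone susD, an
  antiparallel susC/susD, and 20 single-tool CAZyme votes below the
  consensus threshold). Feature zones are kept ≥25 ranks apart so planted
  calls are unambiguous and decoys cannot create accidental PULs.
* **LFQ**: 2,000 proteins, 2 conditions × 3 replicates, base log2
  intensities N(25, 2) (MaxQuant LFQ scale), replicate noise 0.3 log2
  units (≈20 % CV; the "tight variance" scenario used for sensitivity
  checks uses 0.1), 5 % affected proteins at |log2 effect| = 4, and
  left-censoring below log2 = 21 (≈2 % baseline missingness). Censoring is
  MNAR by construction — the mechanism that justifies constant-0
  imputation. Note that planted *down* effects that land partially below
  the censoring limit are genuinely hard for any imputation-based test:
  one or two censored replicates inflate the within-group variance and can
  mask the effect. This is why difference-accuracy is assessed on fully
  quantified proteins and sensitivity under the tight-variance scenario.
* **Images**: 512×512 8-bit pair, 150 non-overlapping disks (radius 3–5 px),
  DAPI 180 on background 10; substrate background 20 with positives at
  +40 gray units over 80 % of their area (above the 30 % overlap rule but
  below full coverage, so the rule is exercised); Gaussian noise sd 2.
* **Growth**: logistic curve, r = 0.09 h⁻¹, OD from 0.01 to 0.5, sampled
  every 2 h for 96 h (manual side-arm photometer cadence), multiplicative
  log-normal noise sd 0.02.

What passing on these conditions does *not* show: real dbCAN/CDD hit
tables have correlated tool errors and fuzzier family boundaries; real
LFQ matrices have peptide-level structure, batch effects and heavier
tails; real micrographs have uneven illumination, touching cells and
focus drift; real growth curves have lag phases and diauxie. The
generators deliberately omit all of these, so the validations certify the
*rules and statistics*, not robustness to instrument artifacts.

## Validation problem sizes

The test suite checks the PUL caller against an independent brute-force
predicate scan on 200 seeded ~2,000-gene genomes, exact planted-PUL
recovery on 50 genomes, the s0 = 0 reduction on 1,000 random draws, FDR
control on 20 null runs of 2,000 proteins (realized false-positive
proportion vs the nominal 0.05 with its binomial 95 % allowance),
≥95 % sensitivity on tight-variance planted effects, growth-rate recovery
over 100 seeds, uptake recovery within ±5 points at planted 0 %/10 %/90 %,
exact motif-scan agreement with naive substring search on 1,000 random
sequences, the full GH16 domain-presence rule grid, and byte-identical
reruns of every CLI stage. `scripts/acceptance.py` re-measures the
headline quantities at the same or moderately reduced sizes (25 genomes,
20 null + 5 effect LFQ runs, 50 growth seeds) in a few seconds.

## Known limitations

* The permutation-FDR estimator is the SAM-style median-count form;
  Perseus' exact volcano-curve parameterization differs in detail and is
  not published, so numerical agreement with Perseus output is expected
  only qualitatively.
* With 3-vs-3 designs the permutation null has only 20 support points;
  the FDR estimate is coarse and conservative in practice.
* The GH16 architecture classifier consumes externally produced domain
  tables; it validates layout and the WPA site but does not predict
  domains from sequence.
* `detect_suscd_pairs` resolves ambiguous layouts greedily; alternative
  maximal matchings are not enumerated.
* Spliced/joined CDS are reduced to their outer span.
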