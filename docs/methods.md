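# Methods

## The assay being modelled

A pooled sensor-effector screen couples, on one vector, an activity
reporter (enhancer → luciferase + unique 35-nt RNA barcode) and an shRNA
effector. Cultures are split into a silenced condition (TTX cocktail),
which takes reporter output to baseline and therefore measures each
vector's abundance, and a stimulated condition (BIC cocktail), where
reporter output additionally reflects pathway activity under that vector's
knockdown. Sequencing the barcode pool in both conditions yields, per
shRNA, a stimulated/silenced expression ratio; knockdown of a positive
regulator lowers it, knockdown of a negative regulator raises it. A
companion multiplexed profiling assay reads a panel of ~70 barcoded
cis-regulatory reporters (three barcode replicates each, plus
minimal-promoter-only calibrators) across untreated, silenced, and
stimulated (2/4/8 h) conditions.

## Generative model of the synthetic screens

The generator (`simdata`) is the package's substitute for raw sequencing
data; its defaults are the reference study conditions and are not tuned
per analysis.

For vector *i* in sample *j*, the expected count is

    μ_ij = depth · w_i · r_j                          (silenced)
    μ_ij = depth · w_i · r_j · F · 2^{δ_i}            (stimulated)

with

* `w_i = a_i / Σa`, `a_i ~ LogNormal(0, σ_a)` — vector representation,
  shared across all samples (replicate cultures are infected from one
  pool);
* `r_j ~ LogNormal(0, σ_r)` — per-replicate multiplicative depth noise
  (a whole-column factor; total-read normalization removes it exactly);
* `F` — sensor induction of the stimulated state (default 21-fold);
* `δ_i` — the planted log2 knockdown effect of shRNA *i*: 0 for null
  genes, `N(−1.0, 0.3)` for positive regulators, `N(+0.8, 0.3)` for
  negative regulators; all shRNAs of a gene share its class, magnitudes
  vary per shRNA;
* counts `K_ij ~ NB(μ_ij, α)` via gamma–Poisson mixing, variance
  `μ + αμ²` (α = 0 degenerates to Poisson).

`depth` is defined as the read yield of a baseline-activity column, so
stimulated columns total ≈ `F · depth`: the induction is visible in raw
read totals, exactly as barcode RNA is more abundant in stimulated
cultures, and is removed by per-sample normalization downstream. A
consequence used as a test oracle: the expected stimulated/silenced count
ratio of a vector is `F · 2^δ` (10.5 for δ = −1, F = 21).

Reads are emitted one per counted molecule with layout
`[12-nt sample code][8-nt flank][barcode][8-nt flank]` and i.i.d. per-base
substitution errors (default 0.005). Assignment amplicons are 345 nt with
barcode and 21-nt guide between fixed anchors. Flank/anchor sequences are
fixed constants of this artifact, chosen for unambiguous anchored
extraction; read length and primer layout of any particular sequencing
chemistry are not modelled.

### Parameter defaults and their rationale

| parameter | default | units | rationale |
|---|---|---|---|
| n_genes | 200 | genes | desk-scale stand-in for the 4,625-target library |
| shrnas_per_gene | {5, 6} | — | library design |
| frac_pos / frac_neg | 0.10 / 0.05 | fraction of genes | screens find more positive than negative regulators under near-saturating stimulation |
| effect δ (pos) | N(−1.0, 0.3) | log2 | reproduces the reported hit log2FC range (≈ −0.2 … −1.4) |
| effect δ (neg) | N(+0.8, 0.3) | log2 | weaker, mirroring the assay's reduced sensitivity upward |
| induction_fold F | 21 | fold | measured sensor induction, stimulated vs silenced |
| abundance σ_a | 1.5 | ln-scale SD | wide post-cloning/packaging representation; reproduces the reported within-condition replicate correlation regime (Pearson > 0.97 on log counts) together with α below |
| dispersion α | 0.05 | — | count overdispersion of biological replicates |
| replicate σ_r | 0.1 | ln-scale SD | sample-to-sample depth wobble |
| depth | 2×10⁶ | reads/baseline sample | ≈ 1,800 reads per vector at 1,108 vectors |
| n_replicates | 3 | per condition | study design (2–3) |
| error_rate | 0.005 | per base | typical raw error of the modelled platform |

What the generator does **not** emulate: PCR amplification bias and cycle
chemistry, indel sequencing errors (substitutions only), multiple
infection per cell, cell-to-cell heterogeneity and network-level coupling
between perturbations, and guide-specific off-target effects. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated count model, not robustness to those real-data pathologies.

## Read processing

* **Demultiplexing.** A read is assigned iff exactly one sample code is
  within `max_code_mm` (default 1) Hamming distance of its first 12 nt;
  ties are unassigned. Sample sheets are validated so codes are pairwise
  more than `2·max_code_mm` apart, making double assignment impossible.
  Conservation (assigned + unassigned = total) is asserted and logged.
* **Barcode matching.** Exact hit wins; otherwise the unique reference at
  minimal edit distance ≤ `max_edit` (default 2) wins; ties are ambiguous
  and discarded (never fractionally split). The implementation is tiered —
  exact hash, Hamming-1 neighbor table, full edlib scan — and is provably
  identical to a brute-force scan: between equal-length strings edit
  distance 1 is achievable only by substitution, so the neighbor tier
  resolves distance-1 uniqueness exactly, and every other case falls
  through to the full scan. Anchors tolerate 1 mismatch; reads are
  processed in the emitted orientation only.
* **Assignment.** Per observed barcode, guides vote; majority wins if
  support ≥ `min_reads` (3) and purity ≥ `min_purity` (0.8), ties and
  impure barcodes are ambiguous. Barcodes are semi-random and unknown a
  priori, so error-derived spurious barcodes are expected and removed by
  the support threshold; guides come from a known collection and are
  error-corrected to a unique Hamming-1 neighbor before voting. The
  thresholds are exposed on the CLI; with defaults the simulator's
  full-gene-recovery regime is attainable (measured 100% gene recovery,
  ≥ 97% of barcodes assigned at 10 reads/vector and 0.5% error).

## Normalization chains

Screen chain: sum barcode counts per shRNA → scale each column to 10⁶
(counts per million) → mean over replicate samples → per-shRNA
`log2((b+p)/(t+p))` with pseudocount p = 0.5 CPM (zero protection; the
underlying pipeline's zero handling is not documented, so the value is a
package choice and CLI-exposed).

Profiling chain: CPM → divide each column by the mean of its calibrator
rows (calibrator mean ≡ 1 afterwards) → mean over the three barcode
replicates per sensor → mean over sample replicates → log2 versus the
untreated reference. On the calibrator-normalized scale typical values are
O(1), so the pseudocount is specified in *reads* (default 0.5) and mapped
onto that scale via the median value of a single read; a fixed 0.5 would
compress genuine fold changes roughly twofold at typical depths.

Chain order is enforced through provenance tags carried by every matrix
(calibrator normalization rejects non-CPM input; condition log-ratios
reject non-collapsed input). Replicate collapse averages normalized
counts, not logs.

## Enhanced Z-score and gene collapse

`z = (r − median r) / (1.4826 · MAD r)`, with a standard-deviation
fallback when MAD = 0 and an all-zero result when both scales degenerate
(≥ 3 finite values required). The underlying method is cited in the
literature without formulas; this robust variant is insensitive to the
heavy-tailed hit distribution, and downstream checks are deliberately
rank-based rather than value-based. Genes are scored by the
strongest-effect rule (min z for the positive direction, max z for the
negative); collapse operates on shRNA-level scores after barcode
summation. Hit direction is fixed: negative z / negative log2FC =
candidate positive regulator; hit cutoffs (|z| ≥ 3 boundary-inclusive,
FDR < 0.05, NA never a hit) are defaults, not constants.

## NB-Wald differential test

A deliberately simplified relative of DESeq2: median-of-ratios size
factors (rows containing zeros excluded from the median); per-feature
method-of-moments dispersion from within-group variances,
`α = (v − m·mean(1/s)) / m²`; group means by vectorized Newton ML at fixed
α (for equal size factors the MLE is the plain normalized mean; all-zero
groups are floored at half a normalized read, so no NaNs); Wald statistic
`ln(q_B/q_T) / SE` with `SE² = 1/I_A + 1/I_B`, `I = Σ μ/(1+αμ)` at the
MLE; two-sided normal p; BH over features passing a mean-normalized-count
filter (default 5), others report NA.

**Dispersion pooling.** With 2–3 replicates per group a per-feature
moment estimate has ~4 degrees of freedom; plugging it into a Wald
statistic behaves like a t₄ treated as normal and inflates type-I error to
≈ 0.12 at nominal 0.05 (measured). The default therefore averages the
per-feature moment estimates into one common α̂ — exact for the
generator's shared-dispersion model and the limiting case of
shrinkage-toward-a-trend, which this package intentionally does not
implement (no Cook's-distance outlier handling or independent-filtering
optimization either). Measured type-I error at nominal 0.05 is
0.044–0.057 across seeds on the 10,000-feature null. `per-feature` mode is
available for data with genuinely heterogeneous dispersion. In the α → 0
limit the statistic agrees with the two-group Poisson score test
numerically; on simulated screens the Wald ranking is cross-checked
against pydeseq2 (log2FC correlation > 0.95, rank ρ > 0.9).

## Sensor profiling

Dynamic range = FC(BIC 4 h) − FC(TTX), descending, ties broken by sensor
id. Kinetic classes (thresholds are package choices, CLI-exposed;
the categories are named in the field without formal rules):
nonresponsive if peak FC < 1.0 log2; amplified if still rising at 8 h
(FC₈ > FC₄ ≥ FC₂ − 0.1); transient if FC₈ < 0.5 · peak; sustained
otherwise — exhaustive and mutually exclusive by construction. Per sensor
and timepoint a two-sided Mann–Whitney test compares silenced vs
stimulated observations — one observation per barcode replicate and
sample, each as that barcode's log2 change over its own reference mean
(using raw normalized values instead would mix in per-barcode abundance
and cost most of the power); exact U distribution for group sizes ≤ 8
without ties, normal approximation with tie correction otherwise; BH
across sensors per timepoint. Knockdown profiles are normalized to the
non-targeting control by subtraction on the log2 scale. The untreated
reference duplicates are averaged before ratios, like every other
replicate group.

## Overlap and enrichment statistics

Hypergeometric tails are computed in log space
(`logsumexp` over `logpmf`), exact for k = 0 (p = 1) and monotone in k;
list-vs-universe consistency is validated. Over-representation analysis
restricts each GMT set to the supplied universe (case-insensitive symbol
harmonization), reports NA for sets disjoint from it, and BH-adjusts
across tested sets. The universe for overlap tests is explicit everywhere
(CLI `--universe`); the published top-100 overlaps are evaluated against
the library's stated 4,400-gene universe.

## Determinism and numerics

One master seed; per-stage generator streams derived via a CRC-keyed
`SeedSequence` spawn, so adding a stage never shifts existing streams.
Identical configuration and seed reproduce libraries, count matrices,
FASTQ files, and whole output bundles byte for byte (manifests contain no
timestamps). Newton iterations for the NB mean cap steps at ±1 on the log
scale and stop at 1e-12; BH uses a stable mergesort; hierarchical
clustering (average linkage on 1 − ρ) pre-sorts samples by id so
tie-breaking never depends on input order; Pearson QC correlations are
computed on log2(x+1) by default (flag-exposed — whether the original
heatmaps used a log scale is not stated).

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own reference conditions: 200-gene screens
(≈ 1,100 vectors) at 2×10⁶ baseline reads for recovery/concordance
statistics; a 10,000-feature null for calibration; a 2.2-million-read
FASTQ round trip at depth 10⁵ for fidelity; enumeration oracles at
N ≤ 12 (hypergeometric) and 1,000 reads (edit-distance scan). Full-library
scale (4,625 targets, >10⁸ reads) changes only constants, not code paths.

## Known limitations

* The NB test's pooled dispersion is correct for the simulator and for
  roughly homogeneous screens, but underfits feature-specific dispersion;
  no shrinkage middle ground is provided.
* The enhanced Z-score is a defined variant, not a reproduction of the
  cited method's unpublished formula; only rank behaviour is claimed.
* Matching assumes single-orientation reads and substitution-dominated
  errors; no quality-aware or paired-end logic.
* Desk-scale screens make top-k overlap statistics coarse (k = 100 of 200
  genes); the analytic overlap results are computed at the published list
  sizes instead.
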