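# Methods

This note records the statistical models, the numerical choices and the
design decisions behind each stage, and what the synthetic benchmarks do
and do not establish about real data.

## Data model

Counts are gene × sample integer matrices; the sample sheet (species,
phase, stage, replicate) is the single source of truth for sample metadata
and the counts header must match it exactly. Sporophyte samples carry a
stage in 1..4; gametophyte samples carry a free stage label and are treated
as one pooled group throughout (the analysis contrasts phases, not
gametophyte stages). Alignment hits use the 12-column tabular convention
with 1-based inclusive coordinates; an optional 13th column (or a separate
id → length table) supplies query lengths. Coverage filtering without a
query length is a hard error at filter time — a silent default would make
the 80%-coverage rule meaningless.

## Low-count filter and normalization

Genes with a summed count below 10 across all samples are removed (the
boundary is inclusive: a total of exactly 10 survives). Size factors are
median-of-ratios: reference genes are those with nonzero counts in every
sample, each sample's factor is the median over reference genes of
count / per-gene geometric mean. Rescaling one library by c multiplies its
size factor *relative to every other sample* by exactly c; the absolute
factors shift by c^(−1/n) because the geometric-mean pseudo-reference
moves with the data. Fold-change estimates are invariant under such
rescaling up to the fold-change pseudo-mean (below), which is negligible
at realistic counts.

## The negative-binomial test

The differential-expression stage is written in-package as the classical
NB2 scheme rather than as a wrapper, so the repository implements what it
tests. Per gene:

* **Dispersion** α by method of moments on normalized counts with the
  residual variance pooled within the two phase groups,
  α = max((v − m̄)/m̄², 10⁻⁸). The floor keeps the Poisson limit
  well-defined; no trend shrinkage is applied — the stage is calibrated by
  planted-truth recovery, not by equivalence with any external package.
* **Group means** q (per unit size factor) solve the NB score equation
  Σᵢ (yᵢ − sᵢq)/(1 + αsᵢq) = 0 by bracketed root finding (Brent), which is
  the exact one-factor NB GLM MLE with log link and size-factor offsets.
* **Fold change** log₂FC = log₂((q_sporo + ½)/(q_gameto + ½)). The
  pseudo-mean of 0.5 normalized counts bounds the fold change when a group
  is all zero, without dropping genes.
* **Wald p** from log₂FC/SE against the standard normal, with
  SE² = (1/I_s + 1/I_g)/ln²2 and the Fisher information
  I = Σᵢ μᵢ/(1 + αμᵢ) evaluated at the pseudo-mean-adjusted group means so
  the SE stays finite for all-zero groups (never NaN).
* **BH adjustment** (statsmodels step-up), and the preferential call
  p_adj ≤ 0.05 ∧ log₂FC ≥ 2 with both boundaries inclusive.

Calibration on generator output: a 2,000-gene null simulation yields a
preferential fraction of essentially zero (well under the 7% tolerance —
the log₂FC ≥ 2 requirement dominates), and genes planted at log₂FC = 3,
μ = 200, α = 0.05 with 3 + 3 samples are recovered with sensitivity ≈ 1 and
a mean estimate within 0.1 of the plant. The small negative bias
(≈ −0.09 at a 10% DE fraction) is a property of median-of-ratios itself:
the planted DE mass shifts the per-sample ratio median slightly, which is
why the planted genes are embedded in a null majority.

## Homology classification

Evidence precedence is orthogroup > protein hit > genome rescue:
orthogroup membership spanning both species is the primary criterion, a
filtered cross-species protein hit (E ≤ 10⁻⁶, query coverage ≥ 80%,
similarity ≥ 35%) the more relaxed fallback, and a protein-vs-genome hit
at the same thresholds rescues genes missing from the other species'
annotation. Coverage is the query span (q_end − q_start + 1)/query_length;
hits are judged independently (no HSP tiling) and one passing hit
suffices. The similarity column of the hit table is used as given
(identity or positives, whichever the producing search reported), since
hit files differ in which they carry. One-to-one orthologs are orthogroups
with exactly one member per focal species. Enrichment of species-specific
genes among preferential genes uses the 2×2 Pearson χ², df = 1, without
continuity correction — appropriate at genome-scale counts and matching
the magnitude such tables produce.

## Expression landscape

Stage matrices are per-gene means of count/size-factor over replicates.
Standardization is the per-gene z-score with the n−1 denominator;
zero-variance genes cannot be standardized and are dropped with a report.
PCA is the SVD of the column-centered observation × gene matrix
(scikit-learn, full solver), with replicate-level samples as observations
and gene subsetting applied before centering; a stage-mean variant is
available by passing stage matrices instead. The divergence matrix is
Spearman's ρ (average ranks on ties) per stage pair over one-to-one
orthologs with nonzero stage-mean expression in both species, computed on
log₂(x + 1) — the offset-1 base-2 log is the conventional choice for
count-scale data; rank correlation makes the result invariant to any
strictly monotone per-species transform anyway. Cells with fewer than 3
usable pairs are reported missing rather than estimated.

## Fuzzy c-means and shift classification

FCM minimizes J = Σᵢⱼ uᵢⱼᵐ‖xᵢ−cⱼ‖² by alternating the membership update
uᵢⱼ = 1/Σₗ(dᵢⱼ/dᵢₗ)^(2/(m−1)) and the weighted centroid update, on
standardized profiles with Euclidean distance (the standard choice for
expression time courses). Numerical details: membership rows sum to 1 to
1e−9; a profile coinciding with a centroid gets full membership there
(split equally over coincident centroids); distances are scaled by the row
minimum before the negative power so near-duplicate centroids cannot
overflow; convergence is max membership change < 10⁻⁶ or 500 iterations;
10 seeded restarts (centroids initialized at k distinct profiles) keep the
best objective, making fits reproducible under a fixed seed. The recorded
objective history is non-increasing, as alternating minimization
guarantees.

The fuzzifier is estimated from the data dimensions with the empirical
formula m = 1 + (1418/N + 22.05)D⁻² + (12.33/N + 0.243)·
D^(−0.0406 ln N − 0.1134) (the standard fuzzifier-selection rule for
expression time-course clustering); it exceeds 1 and decreases in N. The
cluster number comes from the Dmin profile (minimum pairwise centroid
distance over k = 4..40): the default is the override k = 12, otherwise
the first k whose relative Dmin decrease to k + 1 falls below 0.1.

Direction of analysis is configurable; by default the species with the
more complex sporophyte is clustered and the other projected, since its
richer stage structure anchors the centroids. Projection applies the
membership formula with the fitted centroids and fuzzifier to the other
species' standardized ortholog profiles; hard assignments are argmax
membership with ties to the lowest cluster index.

Major clusters condense centroid peaks: stage 1 → early, stages 2–3 → mid,
stage 4 → late. A centroid with two local maxima at non-adjacent stages
whose heights differ by less than 0.1 (standardized scale) is genuinely
ambiguous in timing and stays unassigned; this makes explicit a judgement
that is otherwise made by eye. A pair is excluded from the
conserved/heterochronic call when either gene sits in an unassigned minor
cluster or has max membership below 0.3 (a membership floor of 0.3 demands
roughly three times the uniform membership at k = 12); both knobs are
exposed. Summary percentages are reported over the non-excluded pairs,
matching how an assigned set is described. The pre-clustering filter keeps
one-to-one orthologs that pass the low-count filter in both species and
have nonzero stage variance in both — the minimal requirements for a
standardized profile to exist on each side.

The transcription-factor contrast intersects a TF id list (either
species' ids) with the called pairs and tests TF vs non-TF ×
conserved vs heterochronic with the same 2×2 χ².

## The synthetic generator

The generator emulates the comparative design end to end: two species,
1,000 shared one-to-one orthologs and 200 species-specific genes per
species by default, four sporophyte stages × three replicates plus six
gametophyte samples, NB2 counts with dispersion 0.05 and baseline mean
200, per-sample size factors log-uniform in [0.5, 2] to exercise
normalization. Twelve temporal archetypes (three peaking per stage,
grouped early/mid/late) were designed once by constrained annealing so
that their standardized shapes are mutually well separated (minimum
pairwise distance 1.33) and each peak dominates the stages of other major
phases by ≥ 0.35 — the planted major-phase labels are therefore
unambiguous. Multiplier profiles are 1 + 0.6·shape and average exactly 1
across stages, so planted log₂ fold changes are exact in expectation.
A configurable fraction of orthologs (default 30%) swaps the species-B
archetype to a different major phase (the planted heterochronic shifts,
exact in count by construction); a configurable fraction of genes gets a
sporophyte-wide fold change (default log₂FC 3 on 10% of genes).
Gametophyte samples carry the archetype-free baseline: the generator
plants no gametophyte temporal structure. Shared orthologs are emitted as
1:1 orthogroups and reciprocal filtered-passing hits; species-specific
genes get neither. All randomness flows from the single config seed.

What passing the benchmarks shows — and does not. Recovery of planted
clusters (ARI ≥ 0.8), shift calls (sensitivity/specificity ≥ 0.9,
recovered fraction within 5 points of the plant) and planted fold changes
demonstrates that the machinery is correct and well calibrated under the
stated noise model. Real data differ in ways the generator does not
emulate: expression profiles form a continuum rather than twelve discrete
shapes, dispersion varies per gene, orthology calls carry errors, stages
are sampled imperfectly, and batch structure exists. The benchmarks
validate the method, not any biological conclusion.

## Parent-child GO enrichment

Annotations are closed over the `is_a` DAG (true-path rule) before
testing. For term t with parents pa(t), the union variant pools the
parents' gene sets: p = P(X ≥ k) with X hypergeometric over
(M = |genes(pa)|, K = |genes(t)|, N = |study ∩ genes(pa)|) and
k = |study ∩ genes(t)|. The union variant is the common default of the
parent-child family; the intersection variant differs only for multi-parent
terms and was not needed. Root terms get p = 1 (no parent to condition
on). The universe is the set of expressed genes; only Biological Process
terms are tested by default; term lists are reported at raw p ≤ 0.05
without multiple-testing correction, and redundancy reduction of related
terms is out of scope.

## Pipeline and reproducibility

The orchestration runs filter → DE → homology → landscape →
cluster/project/compare → enrich, writes every intermediate table as TSV,
logs one line per stage with row counts, and records a manifest (config,
package and numpy versions, seed). Any stage failure aborts with a
stage-labeled error. Identical config and seed reproduce every output file
byte for byte.

Benchmark problem sizes (1,000 orthologs for shift recovery, 2,000 genes
for the null calibration, 500 planted genes among 5,000 for fold-change
recovery) were chosen as the smallest sets at which the scored quantities
are stable across seeds; the full suite runs in seconds.

## Known limitations

* The NB test is a deliberately simple stand-in: no dispersion shrinkage
  toward a mean-variance trend, no outlier handling, single-factor design
  only. It is calibrated, not equivalent to any particular established DE
  tool.
* Shift calls are hard (argmax membership with a floor); a
  membership-weighted soft call is not implemented.
* Major-cluster condensation assumes exactly four stages; other designs
  need a custom stage → phase map.
* Multi-copy orthology (paralog-aware comparison) is out of scope; only
  one-to-one orthologs are compared across species.
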