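# Methods

## Data model

An `ExpressionMatrix` is a features × samples table with a declared scale
(`lfq_linear`, `lfq_log2`, `cpm`, `cpm_log2`, `zscore`) and an explicit
boolean missingness mask; a separate imputed mask records provenance so
that analyses which depend on the missingness signal (stage detection,
the core proteome) can refuse imputed input. Sample metadata live in a
`SampleSheet` (timepoint, stage, replicate, species, optional sex) with
the invariants: one stage per timepoint, unique (timepoint, replicate,
species). CPM matrices are consumed pre-computed; the package does not
re-derive them from read counts. Missing cells in files are the empty
string or `NA` on read and the empty string on write, so write∘read is
the identity on values, mask and ids.

## Left-censored imputation

Proteome missingness is treated as missing-not-at-random truncation at
the low-intensity end. Missing log2 LFQ cells are drawn as
`loq − w·(1 − B)` with `B ~ Beta(α, β)`: a beta distribution whose
support is shifted so its upper edge sits at the limit of quantitation.
The anchor `loq` defaults to the 1st percentile of observed intensities,
the window `w` to 10% of the observed range, and (α, β) are fitted by
method of moments on the observed values min–max-rescaled to [0, 1].
These defaults make the procedure fully explicit and seedable; the true
shapes used by any particular upstream pipeline are generally not
recoverable, so exact numeric reproduction of someone else's imputed
values is out of scope by construction. The limit of detection used to
*display* unquantified timepoints (`timepoint_means(..., lod_fill=...)`)
is a separate convention, default 22.5 log2 units; it never feeds the
imputation. Both the imputed and the LOD-filled path are exposed.

## Dynamicity (Gini ratio)

`G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² μ)` over a gene's per-timepoint
quantifications, computed by the exact sorted-vector identity (O(n log n))
with an early return of exactly 0 for constant vectors; unit tests pin it
to the literal double sum at 1e-12. G is scale-invariant and lies in
[0, 1] for nonnegative input. **The score is taken on linear
quantifications**: `gini_table` exponentiates log2-scale matrices first
(overridable with `on_linear=False`). On log2 intensities in the 22–33
range the normalized mean difference is ~0.03 even for strongly dynamic
genes, so the conventional 0.1 stable/dynamic threshold only partitions
meaningfully on the linear scale. Ties at the threshold are stable.

## Variability filtering and stage detection

Temporal variability is the IQR of a feature's timepoint means. "Top P%"
keeps features whose IQR is ≥ the (100−P)th linear-interpolation
percentile of all features' IQRs, zero-IQR features included; ties at
the cutoff survive, so P=100 keeps everything. Conventional settings:
top 90% for clustering inputs, top 30% for the compact transcript
heatmap, top 70% (union over species) for cross-species work.

Stage detection uses the non-imputed mask: a feature is detected in a
stage iff observed in ≥ `min_reps` replicates (default 1) of at least one
of that stage's timepoints. The replicate rule underlying published Venn
counts of this kind is usually unstated, so it is a parameter, not a
constant. Core = detected in all stages.

## SOM stage clustering

Profiles are z-scored per feature with the population sd (divisor n, so
hand examples are exact); constant features are dropped with a warning.
The SOM is the plain online algorithm: codebook initialized by seeded
sampling of data rows; per iteration one random feature updates its
best-matching unit and all grid cells within the (bubble) neighborhood
radius; learning rate decays linearly 0.05 → 0.01 and radius
⌈max(grid)/2⌉ → 1 over the configured 1000 iterations; final assignment
is nearest codebook with ties to the lowest cell id. These schedules are
a deliberate fixed choice — published SOM analyses rarely state theirs,
and a pinned, seedable schedule makes every downstream number
reproducible. Grids default to 4×4 per layer and 5×4 for the joint
transcript+protein map. Exact kept-cluster counts after refinement are
data- and seed-dependent and are not treated as reproducible targets.

Refinement pools all feature-to-BMU distances, takes their 75th
percentile, and keeps a cluster iff its mean member distance is strictly
below that threshold; empty clusters are dropped, features of dropped
clusters leave the analysis set (they are not reassigned). This is
monotone: lowering the percentile never enlarges the kept set. A
member-level variant (additionally dropping individual far features) is
available behind `member_level=True`.

Stage labels: a kept cluster is labeled with stage S iff its member-wise
median z-profile peaks at a timepoint of S **and** its mean over S
exceeds its mean over every other single stage by more than the margin
(default 1.0 z). Comparing against the best competing stage, rather than
the pooled complement, is what keeps a profile with two equally high
stages unlabeled — with a pooled complement a strong two-stage profile
can clear any reasonable margin, which contradicts the intent of
"stage-specific".

## Transcript–protein integration

Gene-wise correlation uses Pearson R over matched timepoint means with
the exact t-transform p-value (`t = r·√((n−2)/(1−r²))`, n−2 df,
two-sided). Classification: positive iff R > 0 and p < 0.05, negative
iff R < 0 and p < 0.05, otherwise none — including constant profiles,
where R is undefined. The conventional pre-filters (protein observed in
≥ 4 replicates of some timepoint, top-90% IQR variability, transcript
CPM > 10 in ≥ 3 samples) are composable helpers rather than baked into
the correlation function, so calibration studies can run unfiltered.

The transcript–protein index of a cluster and stage is the mean over
member genes of the stage-averaged (transcript z − protein z)
difference; mean aggregation is the default with median behind a flag
(profile figures typically show medians, but an index aggregation is
rarely stated). Coherent clusters sit near 0; the index is antisymmetric
under swapping the layers. K-means (Euclidean, k-means++, best of 50
restarts, seeded) groups the cluster × stage index matrix into k = 4
recurring patterns. Transcript/protein cluster overlap is tested per
cluster pair with a one-tailed hypergeometric test over the shared gene
universe, BH-adjusted across pairs.

## Cross-species comparison

Ortholog maps are made strictly one-to-one by removing every pair whose
partner appears more than once on either side. Timepoint grids are
aligned per stage by a normalized moving average — valid-mode
convolution with a uniform kernel of width `w = m − k + 1` — which maps
7 → 4 and 5 → 4 exactly, preserves constants, and shifts a linear trend
by the known `(w−1)/2` phase. Circular convolution (which wraps the time
axis) is available for comparison but rejected as a default: a
developmental trajectory has no periodic boundary. Stages whose lengths
already match pass through unchanged; the default target length per
stage is the minimum of the two species' lengths, overridable per stage,
and specific timepoints can be excluded before alignment. Aligned stage
segments are concatenated in canonical stage order for the per-ortholog
correlation; per-stage correlations use each segment alone (≥ 3 aligned
points required); the all-pairs timepoint × timepoint matrix is computed
on the unaligned grids. Stage-order concatenation, not a curated
timepoint pairing, is the assumption here.

## Differential and enrichment statistics

The early-egg comparison filters to genes with CPM ≥ 1 in ≥ 4 replicates
of either group, tests log2(CPM+1) with a two-sided unpaired t-test, and
calls significance at BH-FDR ≤ 0.05 **and** linear fold change > 2.
Student's pooled-variance test is the default: with five replicates per
group, Welch's Satterthwaite df collapses toward 4 whenever one group's
sample variance happens small, costing real power at the BH cutoff;
Welch remains available (`equal_var=False`). Degenerate genes (zero
variance in both groups) get p = 1 with a logged note. The proteome
variant of this comparison conventionally skips the BH adjustment
(`adjust=False`) because of the lower sensitivity of protein
quantification.

BH adjustment is the vectorized textbook step-up (sort, p·n/rank,
reverse cumulative minimum, cap at 1, unsort), written so that it is
bit-identical to the naive O(n²) definition; agreement with statsmodels
is additionally asserted at 1e-12 in the tests. Term enrichment is the
one-tailed hypergeometric upper tail (two-sided Fisher optional) over an
explicit background — by default the input set of the clustering that
produced the gene sets — BH-adjusted across terms. Maternal-gene
enrichment is a single one-tailed test of the up-set against an
ortholog-mapped reference set, both intersected with the universe.

## Synthetic data: what it does and does not emulate

The generator draws, per gene, a label (one of the four stages or
stable) from configured fractions (default 15% per stage), a log2
baseline, and a coupling ρ (default 0.8). The latent transcript profile
adds a +2 log2 archetype during the gene's stage; maternal genes
(default 10%) get +2 log2 at the first egg timepoint, transcript side
only. Tag counts are negative-binomial (size 10) around the latent means
and normalized to CPM per sample (columns sum to 10⁶ by construction).
The protein z-profile is `ρ·z_tx + √(1−ρ²)·ε` with ε i.i.d. standard
normal over timepoints — every protein therefore carries an independent
temporal component, which is why the Gini classifier marks most
synthetic proteins dynamic — scaled by 2 log2 units onto a baseline
around 26, with Gaussian replicate noise (sd 0.5) and missingness with
probability 0.9 below the 22.5 detection limit (0.02 above). A second
pseudo-species reuses the machinery on a 13-timepoint fly-like grid
(2 egg, 4 larval, 5 pupal, 2 adult); conserved orthologs (default
fraction 0.7) inherit the species-A stage label so their archetypes
match after grid alignment.

Default problem sizes are desk-scale choices: 2000 genes for the
end-to-end pipeline, 6000 for stage-recovery studies, 10⁴ for null
calibration. The generator emulates *structure*, not biology: no
transcription/translation kinetics or protein half-lives, no batch
effects, no sex-specific programs, no count-level library artifacts
beyond NB dispersion, and conservation is binary (shared archetype or
independent). Passing tests therefore demonstrate that the pipeline
recovers the constructs it defines — stage programs, coupling, maternal
boosts, conservation — at realistic noise, not that any particular
biological dataset would yield the same numbers.

## Numerical conventions

Population sd for z-scores; linear-interpolation percentiles everywhere;
Pearson p-values from the exact t-transform (R clipped to [−1, 1];
|t| = ∞ ⇒ p = 0); argmin tie-breaks to the lowest index; BH is
order-preserving with stable sorts. All stochastic components (generator,
imputer, SOM, k-means) accept a seed, and the pipeline derives distinct
per-stage sub-seeds from its master seed so reruns are byte-identical.

## Limitations

Exact reproduction of any published analysis of this design requires the
original data and the unstated hyperparameters of its SOM and imputation
steps; this package instead pins every such choice and verifies the
method's properties on ground-truth simulations. Time-lagged
transcript→protein correlation, protein half-life modeling, nonlinear
trajectory alignment (e.g. dynamic time warping), orthology inference
and rank-based (GSEA-style) enrichment are out of scope.
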