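# Methods

This note documents the models and procedures `exprphylo` implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices and known limitations a user should be
aware of. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and branch identity

The cross-species unit of analysis is the *homology group*: a cluster of
sequence-similar transcripts standing in for a gene across species whose
reference transcriptomes were assembled independently. Homology inference
itself is upstream of this package; the map is an input.

Species trees must be rooted, strictly bifurcating, with positive branch
lengths, and (for ancestral reconstruction on a time scale) ultrametric
within a relative tolerance of 1e-6. A rooted binary tree with n tips has
2n − 2 edges; each gets a stable integer id from a pre-order traversal
with children ordered by their smallest descendant tip label, so ids
depend only on topology and labels, never on newick rotation (with n = 12
this gives the 22 branches used throughout the correlation stage).

When a gene lacks data for some species, its tree is pruned and collapsed
paths are re-matched to the full tree: a pruned edge inherits a full-tree
branch id only when both of its endpoints (identified as MRCAs of their
descendant tip sets) are adjacent in the full tree. Edges created by
collapsing through a removed node have no equivalent and are excluded
from cross-gene comparison. This is deliberately conservative: only
identically-defined branches are ever compared between genes.

## Normalization

TPM is a within-library relative unit and is confounded across species by
reference size, so values are rescaled to TPM10k = TPM x n_ref / 10^4,
where n_ref is the number of genes in the species' reference. What counts
as a "gene" in n_ref is genuinely ambiguous for fragmented assemblies; we
default to the number of homology-group-collapsed genes and expose a
per-species override.

Order of operations: TPM10k → natural log → mean over a homology group's
transcripts per library → mean over replicate individuals per (species,
tissue). Zeros under the log become missing values rather than receiving
a pseudocount; genes with missing cells are excluded from variance
partitioning rather than silently imputed. The only pseudocount in the
pipeline lives in the bias ratio (below).

## Differential expression

The DE stage is a deliberately simple, fully documented negative-binomial
Wald test, not a re-implementation of a shrinkage-based package: the NB
is parameterized by mean μ and dispersion φ (Var = μ + φμ²); φ is
moment-estimated per transcript, pooled across the two tissues and
floored at 1e-8; the effect is log2((m_focal + 0.5)/(m_carcass + 0.5));
its delta-method variance gives a Wald z; p-values are BH-adjusted across
all tested transcripts at α = 0.01. Transcripts that are all-zero in both
tissues are excluded and reported. No per-individual blocking factor is
fit.

Consequences, measured in the test suite: under a global null the
BH-significant fraction stays at the FDR level (≤ 0.012 in a 2,000-
transcript simulation), but without cross-gene dispersion shrinkage the
test is under-powered at n = 3 replicates (sensitivity ≈ 0.26–0.33 for a
true 2-fold change at φ = 0.1; a pilot over seeds 0–5 fixed the test
floor at 0.25), and moment-estimated dispersions make extreme tails
anti-conservative, so the realized FDR in mixed-signal data exceeds the
nominal level. Downstream stages consume only effect signs and adjusted
p-values, and the cross-species cohort rule (≥ min_species of the species
must agree) is itself a strong false-positive filter.

The cohort threshold defaults to "all but two species" (10 of 12 in the
reference design) and is inclusive (≥); both the threshold and direction
are flags.

## Variance partitioning

Per gene, a fixed-effects two-factor model (tissue + species, no
interaction) is fit to the replicate-averaged log values, and sequential
(type-I) sums of squares — tissue entered first — are divided by the
corrected total SS. Because averaging leaves one value per (species,
tissue) cell, the design is balanced and the order of entry is immaterial
(asserted by a test against a factor-swapped oracle). Projections use
SVD-derived orthonormal bases, so the deliberately redundant dummy coding
is numerically safe; proportions are clipped at zero and sum to 1 within
1e-9.

Classification: a gene is *highly variable* when its residual proportion
is below 0.25 (default), or — stricter variant, available via `rule=` —
when a single factor reaches 0.75. Among highly variable genes, SVG means
prop_species ≥ 2 x prop_tissue, TVG the reverse; the two labels are
mutually exclusive by construction. Constant genes and genes with missing
cells are excluded with a status flag, never given proportions.

The clade sweep requires monophyletic tip sets (checked; pairwise mode
deliberately waives the check, since species pairs are rarely clades).
`pipeline.nested_clades` builds a ladder from the shallowest cherry to
the root for designs without a curated clade list.

## Expression-bias evolution

Bias is B = ln((TPM10k_focal + 0.01)/(TPM10k_reference + 0.01)), computed
per replicate individual *before* any averaging so that individual-level
counting-efficiency effects cancel between numerator and denominator,
then averaged over group members and individuals. The pseudocount 0.01
makes zeros well-defined and maps (0, 0) to exactly B = 0.

Ancestral states are maximum-likelihood point estimates under Brownian
motion: the internal-node values minimizing Σ_edges (Δv)²/length,
computed by a two-pass Gaussian message-passing scheme that is linear in
tree size and equal to the GLS solution under the BM covariance (the BM
rate cancels from point estimates; no measurement-error term is fit).
The test suite pins the implementation to a dense normal-equations solve
on 200 random trees at 1e-8. Reconstruction requires more than three
tips with data; tips without data are pruned. Reconstructed values are
convex combinations of tip values and therefore lie within the tip range.

Scaled change on a branch is (descendant − ancestral)/length. A
qualitative *gain* of focal-tissue bias is a branch with ancestral B ≤ 0
and descendant B > 0; a *loss* is the reverse. Because a zero crossing
requires drift across the boundary, crossings concentrate on long
branches under null BM (a seeded rank-correlation test asserts this).
`rank_swings` reports the top-k largest crossings per direction with
deterministic (gene, branch) tie-breaking.

## Coevolution networks

Only genes represented across all species enter the correlation stage, so
every pair shares the same 2n − 2 equivalent branches. The reported
comparison count follows the ordered-pairs-including-self convention G²
(for G = 1,143 full-representation genes this is 1,306,449); the
unordered distinct count is carried alongside. Outlier filtering removes
any gene with a scaled change beyond k·SD (default 2, sample SD with
n − 1 denominator) of the mean over all matrix entries; filtering is
applied before restricting to full-representation genes, and both counts
are logged. Interaction benchmarking uses Welch two-sample t-tests
(pooled-variance available by flag) of each annotated class against 100
fresh random samples of 5,000 unknown-pair coefficients, reporting the
maximum p; symbol pairs collapsing into a single homology group are
dropped; the unknown pool excludes labeled pairs only. Networks are
edges with |r| strictly greater than 0.825, signs retained.

**An important calibration caveat, quantified by the acceptance suite and
left as a deliberately failing test** (`test_null_correlation_distribution`):
although each coefficient is computed from 22 branch values, those values
are linear functions of only 12 tip values (rank 11 after translation
invariance) and are heteroscedastic — a scaled change carries variance
σ²/length, so short branches dominate. The null distribution of r between
independent genes is therefore substantially wider (empirical SD ≈ 0.45
on coalescent-shaped trees) than the textbook Pearson null for 22
independent points (SD ≈ 0.22). Any analysis treating the 22 branches as
independent data points will overstate the significance of strong
pairwise correlations; the interaction t-tests are unaffected in their
validity (they compare two samples of coefficients drawn from the same
construction), but thresholded network edges should be read as ranked
hypotheses, not calibrated significance calls.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at the reference design's scale: 12 species on a random coalescent-shaped
ultrametric tree of depth 1, three tissues (ovary/head/carcass), three
replicate individuals per species, with each individual contributing all
tissues. Per-gene log ovary bias evolves by BM at rate σ² = 0.5 per unit
depth from a root value of 0 (unbiased genes) or N(ln 4, 0.25²) (a
de_fraction = 0.1 minority of truly ovary-biased genes; ln 4 is a
typical magnitude for strongly tissue-enriched genes). Designated pairs
evolve as bivariate BM with per-branch increment correlation ρ = 0.9.
Carcass expected abundances are log-normal (ln-mean 3, ln-SD 1.5); the
ovary expectation is the carcass one times e^bias; heads mirror carcass
unless head bias is switched on. Transcripts fragment with probability
0.2 into 2–4 pieces whose expectations are Dirichlet splits summing
exactly to the parent's. Counts are NB with Var = μ + φμ² (φ = 0.1;
φ = 0 degenerates to Poisson), and libraries are reported as genuine TPM
(sums normalized to 10^6). All randomness flows from a single seed;
identical configurations are byte-identical.

What it does *not* emulate: read-level noise and mapping ambiguity,
sequence evolution, library-size or batch effects, head-specific biology
(by default), incomplete homology maps, or species-specific reference
sizes. A green recovery test therefore establishes that the machinery is
correct on data satisfying the model's assumptions — not that the model
assumptions hold for any particular empirical dataset. Note also that
TPM is compositional: strongly ovary-biased genes depress the TPM of
every other gene in ovary libraries, which induces a small genuine
tissue effect on unbiased genes; this is realistic and visible in the
variance-partitioning stage.

Recovery benchmarks for the correlation machinery (acceptance tests) are
run on noiseless simulated tip biases: NB count noise at the default
levels attenuates pair correlations substantially (to ≈ 0.1–0.2 mean r
for ρ = 0.9 pairs through the full count pipeline), which is itself a
finding about the method's sensitivity to measurement noise rather than
about the correlation estimator.

## Numerical and policy choices

- Tissue labels are a closed enum (ovary/head/carcass/whole); species
  codes are matched case-insensitively.
- All TSVs are UTF-8, tab-delimited, '.' decimal.
- Dispersion floor 1e-8; log2FC pseudocount 0.5; bias pseudocount 0.01;
  atlas pseudocount 2; outlier rule 2 SD; network threshold 0.825
  (strict inequality); α = 0.01 — all exposed as parameters.
- Degenerate inputs fail loudly: polytomies, missing/non-positive branch
  lengths, duplicate transcripts, negative abundances, unknown tissue
  labels and unknown interaction classes are hard errors; self-pair
  interactions and unmapped transcripts are dropped with logged warnings;
  constant genes and zero-variance correlation rows are flagged, not
  silently zeroed.
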