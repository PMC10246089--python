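# Methods

## Correlation layers and interlayer couplings

Expression enters as non-negative TPM, genes × samples, one matrix per
tissue over a shared ordered gene list. Co-expression within tissue α is
the Pearson correlation of log(TPM + 1) across the tissue's samples
(natural log; the base rescales both variables and cancels in r, so it is
purely cosmetic). The +1 keeps zero TPM at exactly zero and damps the
heavy right tail of expression values. Genes with zero variance of
log(TPM + 1) make r undefined; the library raises with the offending gene
ids, and the pipeline drops them with a logged warning before correlating.

Gene selection mirrors the small-N regime of correlation estimation: per
tissue, the top k genes (default 75) by variance of raw TPM, analyses run
on the union across tissues. Ties at rank k break by gene id so the
selection is reproducible. Diagnostics (Jaccard index between
top-by-variance and top-by-mean sets; average mean-TPM rank of the
selected genes) quantify how much the variable genes are also the highly
expressed ones.

The interlayer coupling ω<sub>iαβ</sub> of gene i between tissues α and β
is the same Pearson formula applied to the gene's log(TPM + 1) values on
donors common to both tissues. A donor contributes one sample per tissue
(the first by sample id if several); pairs of layers must share at least 3
donors. Negative couplings are set to zero — the modularity below assumes
non-negative interlayer weights — and the clamp count is logged, because
clamping pure estimation noise leaves a small positive bias
(≈ E[max(N(0, 1/√m), 0)] for m common donors) that acts as weak glue
between a gene's replicas across layers. Intralayer correlations are
*not* clamped.

## The configuration-model null for correlation matrices

The null for layer α is the correlation matrix C maximizing the Gaussian
differential entropy — equivalently log det C — subject to unit diagonal
and per-gene strengths (row sums, diagonal included) equal to the
empirical matrix's. Strict concavity of log-det makes the maximizer
unique. Stationarity forces C⁻¹ to have the form (λ<sub>i</sub> +
λ<sub>j</sub>)/2 off the diagonal with free diagonal entries, so the fit
solves the smooth convex dual over the 2N multipliers: L-BFGS-B (the dual
gradient *is* the vector of constraint violations, so the gradient
tolerance doubles as the fit tolerance) followed by a damped Newton polish
with the closed-form dual Hessian

H<sub>λλ</sub> = (rrᵀ + (1ᵀC1)·C)/2, H<sub>λμ</sub> = C·diag-scaled by
r, H<sub>μμ</sub> = C∘C, with r = C1,

which drives the residual from ~1e−6 to ~1e−12 in a handful of steps.
Defaults: tolerance 1e−6 on the maximum constraint violation, 10,000
iteration cap. Inputs must be symmetric, unit-diagonal and PSD within
1e−8; near-singular inputs (smallest eigenvalue < 1e−6) are ridge-lifted
by 1e−8 on the diagonal and renormalized, with a warning. After
convergence the diagonal is set to exactly 1 and the matrix symmetrized.
Useful identities hold by construction and are tested: the null's log-det
dominates the input's, the fit is permutation-equivariant, equicorrelation
inputs are fixed points, and N ≤ 3 inputs are fully pinned by the
constraints.

Surrogate data from the null are n iid zero-mean Gaussian vectors with
covariance C (Cholesky factorization); their sample covariance uses the
unbiased n − 1 denominator.

## Multilayer modularity and its maximization

Nodes are (gene, tissue) pairs in layer-major order. The supra-modularity
matrix couples intralayer blocks ρ<sub>α</sub> − γ<sub>α</sub>⟨ρ<sub>α</sub>⟩
(diagonal retained: those (1 − γ<sub>α</sub>) self-terms are co-assigned
with themselves in every partition, hence argmax-irrelevant — verified by
running both conventions) with diagonal interlayer entries ω. The
normalization C<sub>norm</sub> sums all ρ entries (diagonal included) plus
all ω entries; ordered pairs are double-counted. A Newman–Girvan variant
accepts multiplex adjacency input (zero diagonal, strengths
k<sub>iα</sub>, per-layer totals m<sub>α</sub>) for externally estimated
sparse networks.

Maximization is generalized Louvain on the matrix: greedy single-node
moves by exact gain (2× the node-to-community B sum difference; ties keep
the current community, otherwise the lowest label; one empty label is
always available so nodes can split off), then exact block aggregation of
B, repeated until no gain; node order is reshuffled per sweep from the
seed. Iterated runs feed the output back as the initial partition until a
fixed point (cap 100 rounds; Q is non-decreasing across rounds).

Two documented weaknesses of single-node local search motivated two extra
Q-monotone passes:

- **Split refinement** (`refine_partition`): once two groups share a
  community, no single node gains by leaving, even when the total
  between-group weight is negative. The pass re-clusters each community's
  induced sub-matrix from singletons and accepts any split whose
  cross-part weight is negative (the global Q gain is exactly minus that
  weight), then lets Louvain re-converge.
- **Pillar moves** (`pillar_moves`): a gene's layer replicas hold each
  other in place through their interlayer couplings — moving one replica
  alone severs the coupling and never gains, even when moving all replicas
  together would. The pass relocates a gene's whole node set at once by
  exact gain. On small two-layer instances where the exhaustive optimum
  requires such a coordinated move, no amount of seeded single-node
  Louvain finds it (observed 0/20 runs); with pillar moves the optimum is
  reached.

Consensus follows the agreement-matrix scheme: co-assignment fractions
over the input partitions, minus the mean agreement of the same partitions
with labels randomly permuted (100 size-preserving permutations; negative
residuals kept as repulsion), clustered repeatedly until all runs agree.
Agreement clustering tracks the modal co-assignment pattern, which on a
diverse ensemble can sit strictly below *every* input run's modularity
(brute-forcing the residual matrix confirms the consensus step itself is
not at fault). The converged consensus is therefore polished against the
original supra matrix: seeded descents (local moves → split refinement →
pillar moves) from the consensus labels, plus a short basin-hopping loop
that perturbs 30% of the labels and re-descends, keeping the best Q. Every
polish ingredient only ever increases modularity in acceptance, so the
consensus structure is the anchor, not a casualty. `detect_communities`
bundles the full stack (default 200 runs, per the reference analysis).

An exhaustive set-partition enumerator (restricted-growth strings, ≤ 10
nodes) serves as the test oracle.

## Resolution selection

With a single γ shared across layers, each partition's modularity is
affine in γ: Q<sub>p</sub>(γ) = (a<sub>p</sub> − γ b<sub>p</sub>)/C<sub>norm</sub>,
where a<sub>p</sub> sums within-community empirical weight (intralayer ρ
plus ω) and b<sub>p</sub> the within-community null weight. The sweep runs
one iterated-Louvain partition per grid value (default: 15 evenly spaced
values on [1, 4]); the upper envelope of the lines tiles the range into
optimality intervals (coincident lines merged keeping the first id;
boundary clipping flagged, since the winning line may extend beyond the
grid). The two widest intervals are the robust resolutions; the
representative is the interval midpoint, with an override to pin any value
inside an interval. Ties in width prefer smaller γ.

## Community significance

The quality of community S is W: the sum of empirical correlations over
within-layer gene pairs inside S (diagonal excluded, unordered pairs). The
null treats layer α's surrogate as the sample covariance of L<sub>α</sub>
Gaussian observations drawn from the fitted null C<sub>α</sub>. Then
E[W] is the same pair sum over C<sub>α</sub>, and Isserlis' theorem gives

Var[W] = Σ<sub>α</sub> (1/L<sub>α</sub>) Σ<sub>(i>j)</sub> Σ<sub>(k>r)</sub>
(C<sub>ikα</sub>C<sub>jrα</sub> + C<sub>irα</sub>C<sub>jkα</sub>),

vectorized as pair × pair Gram products and verified against a literal
quadruple loop to 1e−12. Communities can span layers with different
sample sizes, so 1/L<sub>α</sub> is applied inside the layer sum; with a
common L this reduces to the single-factor form, and Var × L is constant
to machine precision. The closed form uses the 1/L convention while the
Monte-Carlo oracle's sample covariance uses L − 1, so the two agree to
O(1/L) — well inside Monte-Carlo error at the sizes tested. Z = (W − μ)/σ;
communities with no intralayer pairs (or zero variance) carry an undefined
Z rather than an exception, and are flagged in the significance table.

## Specialist/generalist classification and genomic analyses

For each community, a gene is *unique* to tissue α if its node appears in
the community only in layer α. The specialist tissue is the layer with
the most unique genes (ties: all tied layers reported, lexicographically
first used in summaries), and the specialist fraction is that count over
the community's node count: 1 for a community confined to one layer, 0
when every gene spans at least two. Fractions strictly above 0.5 classify
the community as specialist. For genomic analyses a specialist community
contributes all its distinct genes; a generalist community contributes
only genes present in at least 3 layers within it (so the gene plausibly
acts across tissues); duplicate genes across generalist communities are
logged, not suppressed.

Gene coordinates come from BED6 (0-based half-open, converted to 1-based
inclusive; `chr` prefixes stripped, `MT` mapped to `M`; strand ignored).
The pair distance is the base-pair gap between the earlier gene's end and
the later gene's start, 0 for overlapping genes (never negative),
undefined across chromosomes. Three randomization tests against a fixed
background gene set (default 100 replicates):

1. same-chromosome pair fraction x<sub>c</sub>, against shuffles of the
   chromosome labels over the background (one-sided toward enrichment);
2. mean same-chromosome gap d<sub>c</sub>, against redraws of n<sub>k</sub>
   background genes per chromosome carrying ≥ 2 group genes (one-sided
   toward clustering, so significant Z is negative);
3. per-chromosome mean gap for chromosomes with ≥ 3 group genes
   (configurable to 2), with one-sided normal p (needed to report p-values
   below the 1/replicates resolution) and the empirical permutation p,
   Bonferroni-corrected over the group's tested chromosomes (optionally
   over all community-chromosome pairs).

Degenerate randomizations (constant replicates — e.g. the group exhausts
the background) yield an undefined Z, detected with a relative 1e−12
spread threshold because `np.std` of a constant vector returns ~1e−17.

Shared-eQTL discovery intersects the variant sets of every gene pair whose
co-expression exceeds 0.5 in the designated tissue, from a pre-filtered
association table (gene_id, variant_id[, pval_nominal]).

## Synthetic data

Log-expression is a Gaussian factor model drawn per donor, mapped to TPM
by exp(·) − 1 clipped at 0. With the default mean 5 and scale 1, TPM is
essentially always positive and log(TPM + 1) reproduces the planted
correlations (clipping distortion is negligible). Structure:

- a weak **global factor** (loading √ρ_out), drawn per donor and shared
  across tissues, gives all globally expressed genes the background
  correlation ρ_out within and across tissues — emulating donor-level
  covariation common to tissues;
- **generalist blocks** add a block factor (loading √(ρ_in − ρ_out))
  reused across all layers for shared donors, so block genes correlate at
  ρ_in everywhere and carry high interlayer couplings;
- the **specialist block** is driven, in its home tissue only, by a
  private factor *independent of the global one* — mirroring
  tissue-restricted programs whose variation is unrelated to layer-wide
  covariation — so its genes correlate at ρ_in among themselves, ≈ 0 with
  everything else in the home tissue, and behave like background genes
  elsewhere. This orthogonality matters: if specialist-to-rest correlation
  were set at ρ_out instead, the separation term ρ_out − ⟨ρ⟩ would be a
  zero-mean coin flip across draws, and whether the specialist block
  survives as its own community at γ = 1 would be luck.

The planted truth labels generalist blocks across all layers, the
specialist block in its home layer, and everything else — background genes
plus specialist genes outside their home tissue — as one diffuse
cross-layer background community (they all share only the global factor).
Per-layer target matrices are checked positive definite before sampling.
Defaults are the reference scenario: 4 tissues × 60 genes, three 12-gene
generalist blocks, one 10-gene pancreas specialist block, ρ_in = 0.7,
ρ_out = 0.05, 500 samples per tissue, donor overlap 0.5.

Gene loci are placed on synthetic chromosomes (uniform, except designated
clustered groups laid out as consecutive runs with small gaps); the toy
eQTL table gives each gene private variants and planted pairs shared ones.

What the generator does **not** emulate: library-size artifacts, batch
effects, count (negative-binomial) noise, heavy-tailed expression,
realistic gene-density variation along chromosomes, or LD structure among
variants. Passing tests therefore demonstrate correctness of the
algorithms under the stated Gaussian factor model, not robustness to real
GTEx data pathologies.

## Known limitations

- Clamping negative interlayer couplings biases pure noise upward; on some
  synthetic draws this glue makes *merging* the specialist block into the
  diffuse background genuinely modularity-optimal at γ = 1 (verified by
  comparing Q directly on such draws). That is a property of the
  statistic, not of the optimizer; higher resolutions separate the block
  again.
- The diffuse background community's internal placement is nearly
  Q-neutral, so different seeds can partition background genes
  differently without materially changing Q.
- Modularity maximization is NP-hard; all guarantees here are empirical
  (exhaustive cross-checks are limited to ≤ 10 nodes).
- The closed-form variance assumes Gaussian data, as does the
  configuration model itself.

## Problem sizes used in the test suite

Unit tests run on 2-layer, 15–20-gene instances; the end-to-end recovery
test runs the full default scenario (240 nodes, 200-run consensus); the
Monte-Carlo cross-check uses 10,000 replicates at L = 200; optimizer
quality is scored on 50 exhaustive 8-node instances; localization
calibration averages 200 random groups at 100 randomizations each. These
sizes were chosen so the whole suite completes in well under a minute on
one core while keeping every statistical check comfortably powered.
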