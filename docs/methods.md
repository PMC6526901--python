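# Methods

This note documents the models, numerical choices and known limitations of
`imprintsel`. It is written for users who want to understand exactly what
the package computes before trusting it on real data.

## Codon substitution model

The engine is a GY94-style Markov model on the 61 sense codons of the
standard nuclear code (any NCBI table can be injected). The instantaneous
rate from codon *i* to *j* is nonzero only for single-nucleotide changes:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with stationary codon frequencies `pi` estimated from the alignment as
F3x4 (default, position-specific nucleotide frequencies) or F61 (observed
codon frequencies, 0.5 pseudocount). Frequencies are floored at 1e-8 and
renormalised so the reversible-matrix symmetrisation is well defined.

**Branch-length convention.** Every ω-class generator is scaled by the
total rate of the *neutral* (ω = 1) matrix with the same κ and π. Branch
lengths therefore read "expected substitutions per codon site under neutral
composition", and a class with ω > 1 evolves proportionally faster, ω < 1
slower — the rate-elevation signature that branch-site tests depend on is
preserved. This differs from the convention of scaling by the fitted
mixture's average rate: the two differ by a data-dependent constant
absorbed into the branch lengths, and the neutral-reference choice makes
the per-site likelihood of a class a function of that class's ω alone given
fixed branch lengths, which the optimiser exploits (below). The simulator
uses the identical convention, so branch lengths mean the same thing on
both sides of every recovery and calibration check. The standalone
`build_rate_matrix` helper instead normalises a single-ω matrix to mean
rate 1, the usual convention for a one-class model.

Likelihoods are computed by Felsenstein pruning over unique site patterns,
with per-node rescaling against underflow. Gap triplets and IUPAC
ambiguity codes contribute a partial-likelihood vector that is 1 on every
compatible sense codon (missing-data integration). A site whose data are
structurally impossible under a class (e.g. a nonsynonymous difference
under ω = 0) yields −inf for that class and is handled by the mixture's
log-sum-exp; only NaN is treated as a numerical error.

## Model fits

Registered models: M0, M1Neutral, M7, M8, M8a, Model A, Model A null.

- **M0** maximises over κ, ω and branch lengths (per-branch by default;
  global-scale and fixed modes available) with bounded L-BFGS on
  log-transformed parameters and ω starts {0.1, 0.4, 1.5}.
- **Mixture models** hold branch lengths *and κ* at the M0 estimates.
  Fixing branch lengths follows common practice for site-model batteries;
  fixing κ as well is a further economy of this implementation (option
  `reestimate_kappa` turns on a profile iteration over κ). Nesting of every
  LRT pair is unaffected because both members share the same κ.
- **M1Neutral** follows the classic parameterisation with ω₀ = 0 fixed and
  p₀ free; the modern variant with ω₀ estimated in [0, 1) is available via
  `m1_variant="m1a"`. **Model A** is built consistently with the chosen
  variant: classes (ω₀, ω₀), (1, 1), (ω₀, ω₂), (1, ω₂) with ω₂ ≥ 1 on
  foreground branches and the usual proportion structure; the null fixes
  ω₂ = 1.
- **Beta discretisation** uses K = 10 equal-probability classes whose ω
  values are conditional means within quantile bins (so they average
  exactly to p/(p+q)).

**ω-grid acceleration.** Because a class's per-site likelihood depends only
on its ω (given fixed branch lengths and κ), the fitter evaluates exact
per-pattern log-likelihoods once on an ω grid — log-spaced points on
[1e-4, 0.06], linear on [0.06, 1], log-spaced on [1, ω_max = 20] — and
interpolates with cubic splines during optimisation (ω values are floored
at 1e-4; the error of the spline surrogate is far below the optimiser
tolerance of 1e-6 in lnL). The reported log-likelihood is always recomputed
*exactly* at the surrogate optimum, so LRT statistics never inherit
interpolation error; the max(0, ·) guard absorbs the sub-0.01 discrepancies
that exact recomputation can introduce at boundary optima. M8 and M8a runs
are seeded from an internal beta-only fit so the nested optimum is always
reachable. When L-BFGS aborts on a flat surface (common at boundary optima
under null data) a bounded Nelder–Mead polish confirms or improves the
optimum before the converged flag is set.

**LRT degrees of freedom** follow the usual conventions: M8 vs M7 df 2,
M8 vs M8a df 1, Model A vs its null df 1, Model A vs M1Neutral df 2 —
plain χ² upper tails, no 50:50 boundary mixture (conservative for the
df-1 boundary tests).

**Empirical-Bayes posteriors.** NEB evaluates class posteriors at the
MLEs. BEB is implemented for M8: a flat 10 × 10 grid prior over the
positive-class weight p₀ (bin midpoints of (0,1)) and ω_s (log-spaced on
[1, 15]) with the beta shapes held at their MLEs, weights proportional to
the full-data likelihood at each grid point. Model A falls back to NEB
with an explicit `fallback` flag, as does any degenerate grid. Reporting
prefers BEB whenever it is available.

**Pairwise ω** fits M0 on a two-taxon tree (t, κ, ω free) and converts to
dN and dS via the model's substitution-flux fractions and the neutral
site composition (so dN/dS equals the fitted ω exactly). Pairs with no
substitutions, or no synonymous substitutions (dS = 0), report ω as
missing and are excluded from summaries.

## Per-site detectors and consensus

- **FEL-style:** per site, ML fit of a synonymous rate α_s and
  nonsynonymous rate β_s (absolute multipliers of the gene-average branch
  lengths, κ and branch lengths fixed from M0), LRT of β_s = α_s on df 1;
  positive iff β_s > α_s at p < 0.05. Sites sharing a column pattern are
  fitted once.
- **SLAC-style:** marginal ML ancestral reconstruction under the fitted M0
  (ties broken toward the lexicographically smallest codon, so the
  reconstruction is deterministic), pathway-averaged counts of synonymous
  and nonsynonymous changes along branches, and a two-sided extended
  binomial test of the nonsynonymous count against the mean nonsynonymous
  opportunity of the codons present. Fractional (pathway-averaged) counts
  use the regularised-incomplete-beta continuation of the binomial tails,
  which reduces to the exact binomial at integers.
- **Consensus:** a site is confirmed when ≥ 2 distinct methods (NEB/BEB,
  FEL, SLAC) flag it positive at their thresholds, and is then dropped if
  its column has a gap fraction strictly above 0.40. The FEL/SLAC
  significance threshold defaults to the pipeline-wide α = 0.05.

These per-site tests are weak at small taxon counts — with 6–8 sequences
the per-site LRT rarely clears 0.05 even for truly selected sites. The
tests therefore check *ordering* (selected sites get systematically lower
p) rather than raw power, and the gene-level calls rest primarily on the
mixture-model LRTs.

## Recombination screen

Two detectors, one per method family, feed the removal rule "flagged by at
least one substitution-based AND at least one phylogenetic method":

- **MaxChi:** for every sequence pair, the match/mismatch vector over the
  pair's comparable columns is scanned for the breakpoint maximising the
  2×2 χ² of (left/right window) × (match/mismatch); significance by
  permutation of column order. Both the statistic and the permutation
  stream are pair-local, so removing an unrelated sequence never changes a
  pair's result. Both members of a significant pair are reported (the
  pairwise statistic carries no direction), which makes the subsequent
  consensus removal conservative: a recombinant's donor partners can be
  flagged alongside it.
- **Bootscan-style:** per window, bootstrap resampling of columns,
  neighbour joining on p-distances, and the modal nearest neighbour of
  each sequence (the minimal-path-length leaf within its sister clade,
  ties broken lexicographically). A sequence is flagged when its modal
  neighbour changes between adjacent windows with bootstrap support at or
  above the threshold on both sides.

Defaults (window 200, step 50, 100 replicates/permutations, support 0.70,
α = 0.05) are explicit configuration, not reconstructions of any published
run settings.

## McDonald–Kreitman battery

Counting walks codon columns of the aligned haplotypes and outgroup. A
nucleotide site segregating in the population contributes to P_N/P_S; a
site monomorphic in the population but different from the outgroup
contributes to D_N/D_S; a site that is both polymorphic and divergent
counts as polymorphic only (conservative standard convention). Codons with
several changed positions are pathway-averaged over the orderings that
avoid stop codons, giving fractional counts; orderings are anchored at the
population's major codon. Fractional counts are rounded half-up for Fisher
tables only. Accessions missing at a site are excluded from that site's
segregation assessment.

The aggregate battery sums counts over genes (genes with undefined D_N/D_S
or P_N/P_S are excluded from FI, as is standard). eFI is computed as the
FI formula applied to summed per-gene *expected* 2×2 cells under
row/column independence given each gene's margins — an interpretation of
the usual "expected fixation index", flagged in the output metadata and
pluggable; an externally reported eFI can be supplied directly, and
α = (FI − eFI)/eFI holds exactly either way. NI_TG uses the
Tarone–Greenland weighting Σ(D_S·P_N/(P_S+D_S)) / Σ(P_S·D_N/(P_S+D_S)).
Gene classification uses a neutral band |log(dnds/pnps)| ≤ log 1.5, a
"low" ratio threshold of 0.5 and a "high" threshold of 1.0 — explicit
configuration where no standard values exist.

## Gene sets, ages, fixation

Enrichment odds ratios use the Haldane–Anscombe 0.5 correction when a cell
is zero (flagged) and two-sided Fisher exact p-values. Age classes are the
deepest clade index (0 = focal species … 9) with a homology hit at
e-value strictly below 10⁻³. The age-distribution test is exact Fisher on
the class × set table: full recursive enumeration when the conditional
table space is ≤ 2·10⁵ tables, otherwise a seeded margin-conditional
Monte-Carlo (sequential multivariate hypergeometric rows, 20 000 draws).
The fixation check applies all of an accession's alleles to the reference
codon jointly, translates, and compares amino acids, so synonymous
variation never breaks fixation; heterozygous calls (unexpected in inbred
accessions) count as non-reference, missing calls shrink the denominator.

## Synthetic data: what it emulates, and what it does not

The alignment simulator draws root codons from π and evolves them with
exact transition probabilities (matrix exponentials of the same
neutral-scaled generators the engine uses), with per-site classes drawn
from the mixture and optional foreground ω₂ on marked branches. The study
bundle emulates the study design: ortholog clusters of ~8 taxa with the
focal terminal branch as foreground (length ≈ 0.25–0.35 neutral
substitutions per codon), 200-codon genes, a stated fraction (default
30%) under foreground selection at ω₂ = 5, 80-haplotype populations with
an outgroup, control pools with a background PS incidence, and homology
hits for ageing.

The population generator is a *mutation sprinkler*: Poisson numbers of
synonymous/nonsynonymous segregating variants and fixed differences are
placed at distinct codon sites with uniform derived-allele counts. MK
counting depends only on realised variant configurations, so this
suffices for calibrating the battery, but it carries no coalescent
genealogy, no linkage, no recurrent mutation and no indels. Passing tests
therefore demonstrate correct counting and aggregation, not robustness to
demographic structure. Likewise the alignment simulator produces no
indels or alignment error, so the quality-gate tests exercise the scoring
rule, not a realistic misalignment process.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at desk scale,
chosen as the smallest sizes at which each statistical property is
informative: 6-taxon, 200-codon alignments with 200 replicates for the
LRT type-I calibration; 300 codons for M0 recovery; 200 genes × 150
codons × 80 haplotypes for the neutral-FI recovery; 1000 genes for the
enrichment-OR recovery. Every stochastic component takes an explicit seed
and is a pure function of its parameters and seed; pipeline reports are
byte-identical under identical configuration.

## Known limitations

- Branch-site power at a single short foreground branch is modest
  (roughly half of truly selected genes at bundle scale), consistent with
  the general behaviour of branch-site tests on few taxa.
- BEB integrates over (p₀, ω_s) only; the beta shapes are profiled at
  their MLEs rather than integrated.
- The eFI recipe is an interpretation (see above) and can be replaced by
  supplying an external value.
- MaxChi/bootscan consensus can remove a recombinant's donor partner as
  well as the recombinant; for pipeline purposes this errs toward
  excluding sequences, never toward keeping a recombinant.
- No codon-usage selection, no synonymous-rate variation across sites,
  and no indel model.
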