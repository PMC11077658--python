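# Methods

`tealgen` re-implements, as a tested library plus a short analysis
pipeline, the demographic and conservation-genomic toolkit used to assess
a two-population duck system (a small western Mediterranean deme, "ES",
and a much larger south-west Asian deme, "IQ"): coalescent simulation of
a nine-model divergence family, folded joint-SFS composite-likelihood
model selection with AIC, bootstrap confidence intervals, stairway-style
N_e(t) reconstruction, and the standard nuclear (H_O, H_E, pi, F_IS,
KING kinship, Weir–Cockerham F_ST) and mtDNA (Hd, pi, Tajima's D,
Phi_ST, AMOVA, statistical-parsimony network) statistics.  Everything is
exercisable on synthetic data produced by the package itself.

## The demographic model family

Two contemporary demes of haploid sizes θ_ES and θ_IQ split from an
ancestral population T_DIV generations before present.  The ancestral
population is piecewise constant with one ("A"), two ("B") or three
("C") epochs (sizes θ_ANC, θ_BOT1, θ_BOT2, change times T_BOT1 < T_BOT2
looking backwards).  Post-divergence gene flow is absent (SI, model
suffix 1), symmetric (IM_S, suffix 2: one rate m_S) or asymmetric (IM_A,
suffix 3: two rates).  Free-parameter counts are A1:3 … C3:9, with θ_IQ
always fixed externally (below).

**Units.**  All sizes are HAPLOID lineage counts: two lineages in a deme
of size N coalesce at rate 1/N per generation.  This matches the
"haploid individuals" convention of the mutation-scaled estimates the
model family is built around; divide by two for diploid-individual
N_e.  Time is in generations before present; migration rates are
backwards rates (a lineage in deme i jumps to j at rate m_ij per
generation), the convention in which a fitted m_S is reported.
Conversions: years = generations × generation time (default 4 years);
haploid N = π / (2μ) with μ = 4.83 × 10⁻⁹ per site per generation
(an Anatidae rate), so π = 4.70 × 10⁻⁴ gives N ≈ 48 654.

## Coalescent engine

The simulator is an event-driven structured coalescent (exponential
waiting times between coalescence/migration events, piecewise-constant
rates, deme merge at T_DIV), JIT-compiled with numba.  Two kernels:

* a **spectrum kernel** that accumulates, over replicate genealogies,
  the branch length subtending every (i ES-descendants, j
  IQ-descendants) configuration.  Normalised over non-monomorphic cells
  this is the expected folded joint SFS conditional on polymorphism
  (mutations fall on branches with probability proportional to length);
* a **tree kernel** that records parent pointers and node times for
  overlaying mutations.

Nuclear SNPs use an infinite-sites overlay (Poisson mutations per
branch, each creating one bi-allelic column carried by the subtended
leaves), which matches SFS theory.  mtDNA uses one non-recombining
genealogy per dataset and finite-sites Jukes–Cantor mutation, so
reverse/parallel changes (homoplasy) are possible, as in real
control-region data.  A per-replicate event cap (default 5 × 10⁶)
guards against non-coalescing parameter combinations; hitting it raises
an error naming the model.

Calibration tests check Watterson's E[S], the 1/i + 1/(n−i) folded
spectrum shape, expected pairwise diversity, and distributional
agreement (Kolmogorov–Smirnov on tree height and total length) with an
independent coalescent simulator (msprime) for three model types.

## Synthetic data generator

The generator's defaults emulate the study conditions: 24 + 12 diploid
individuals genotyped at 75 000 ddRAD-like loci of 140 bp (yielding
roughly 2 500 polymorphic unlinked SNPs under the fitted model — the
scale of the real panel), 2% missing calls i.i.d. (the real panel kept
~91% of SNPs as complete cases after downsampling, implying low per-call
missingness), diploids formed by
random pairing of haplotypes, and an optional pedigree layer that
appends relatives by Mendelian draws to exercise kinship filtering.
The mtDNA generator emulates the 169 bp control-region fragment
(32 + 12 sequences by default).  Two constants the source system does
not pin down were set once and documented:

* **mtDNA effective-size factor** 0.5 × the deme's haploid nuclear size
  (maternal haploid inheritance);
* **mtDNA mutation rate** 2 × 10⁻⁶ per site per generation, chosen so
  the synthetic fragment reproduces the observed scale of
  control-region variation (π ≈ 0.008, i.e. ~1.4 pairwise differences
  per 169 bp, and ≲15 haplotypes).

What the generator does NOT emulate: within-deme substructure and
inbreeding (each deme is panmictic), linked selection, genotyping-error
structure, and reference-bias artefacts.  Consequences: synthetic F_IS
is ~0 (the real ES deme shows a strong Wahlund effect), and realized
F_ST under the fitted model (~0.02) is below the observed 0.058.  Note
also that the fitted parameter combination itself (recent split from a
small ancestral population) implies a much lower absolute per-site
diversity than the π used to fix θ_IQ — polymorphism-conditioned SFS
shapes do not constrain absolute diversity, so passing tests on
synthetic data demonstrate estimator correctness, not that the fitted
model reproduces every observed summary of real data.

## SFS construction

SNP filters follow RAD practice: call rate ≥ R (default 0.75, computed
over all genotyped individuals in the matrix, as stacks does), minor
allele frequency ≥ 0.01 (inclusive boundary, non-missing calls only; the
MAF floor is DISABLED for SFS building since rare variants carry the
demographic signal), and one uniformly-random SNP per RAD locus.  To
remove missing data exactly as the study protocol does, each deme is
downsampled to 50% of individuals — strategy "least-missing" keeps the
most complete genotypes deterministically (ties by id order); a seeded
"random" strategy is available — and any column still containing a
missing call is dropped.  Folding merges a configuration with its
complement once; complementary pairs on the half-total line carry half
weight each (the dadi convention), the self-complementary cell keeps its
own mass, and monomorphic corners are masked.  A hypergeometric
projection onto smaller sample sizes is provided as an alternative to
individual-level downsampling (mass projected into monomorphic corners
is reported separately).

## Composite likelihood, model selection, bootstrap

lnL(model) = Σ_cells m_cell · ln p_cell in natural log with the
multinomial constant omitted (AIC differences are unaffected).  Expected
cell probabilities come from the spectrum kernel (default 10⁴–10⁵
genealogies), conditioned on polymorphism because invariant sites are
not observed; empty cells are floored at 1/(10 · n_sim) and the table
renormalised, so observed cells never meet log 0.  Because the
polymorphic-only spectrum carries no absolute mutational scale, θ_IQ is
fixed from the IQ deme's all-positions diversity (θ = π/2μ) and the
remaining parameters are estimated.

Optimization replaces ECM cycling with multi-start bounded direct search:
Nelder–Mead on log10 parameters, starting from a "center" start at the
geometric mid-point of the bounds, optional explicit warm starts (a
nested parent model's optimum embedded into the richer model's space via
`warm_start_params` — the standard way to guarantee a richer model never
fits worse than its nested special case), and log-uniform random
restarts; common random numbers within a replicate keep each search
deterministic.  All replicate endpoints AND the explicit start points
are then re-ranked on one common higher-precision simulation surface
whose seed is shared across models fitted with the same top-level seed,
and the champion is polished briefly on that same surface.  Reporting
every model's lnL from one consistent surface makes cross-model AIC
differences meaningful at far smaller simulation counts than independent
noisy evaluations would allow.  Search bounds: sizes 10²–10⁶
haploid, times 10⁰–10⁵ generations, migration 10⁻⁹–10⁻² per generation;
epoch times are parameterised as positive increments past T_DIV so the
ordering constraint holds by construction.  A fit that never improves on
its starts is flagged non-convergent rather than silently returned.

AIC = 2k − 2 lnL; ΔAIC subtracts the minimum; Akaike weights are
ω_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2).  Confidence intervals are percentile
parametric bootstrap: B spectra simulated at the MLE with the observed
polymorphic-SNP count, each refit (reduced replicate count), 2.5/97.5
percentiles per parameter.  Percentile CIs need not contain the point
estimate; none of the machinery "corrects" this.

Default replicate counts in the tests and analysis scripts are reduced
(1–3 starts, 20–50 bootstrap draws) relative to a production protocol
(100/100); both are reachable through function arguments, and the
reduced numbers are the package's own choice of problem size for its
shipped experiments.

## Analytic single-population SFS and stairway-style reconstruction

For one deme with piecewise-constant sizes, E[ξ_b] = Σ_k k·E[T_k]·P(a
lineage among k subtends b of n leaves), with P(b|k) = C(n−b−1,k−2)/
C(n−1,k−1).  The occupancy times E[T_k] of the block-counting death
chain are computed per epoch with an augmented matrix exponential
(transition plus integrated occupancy in one expm), and in closed form
for the final infinite epoch.  The constant-N case reduces to
θ(1/i + 1/(n−i)) with the half-weight fold at i = n/2, and the routine is
cross-checked against the Monte-Carlo kernel.

The stairway-style fit estimates one size per epoch on a fixed time
grid by maximising a Poisson composite likelihood with class means
μ · L_total · E[ξ_b^folded], where L_total is the total sequenced length
(polymorphic and not).  The Poisson form — rather than the
polymorphism-conditioned multinomial — is deliberate: under constant N
the conditioned folded shape is independent of N, so absolute N_e is
unidentifiable without the mutational scale; anchoring on μL restores
it and is exactly what stairway-type methods do.  Uncertainty bands are
2.5/97.5 percentiles over a SNP-resampling bootstrap.

## Nuclear statistics

Per site (non-missing calls only): H_O = fraction heterozygous; H_E =
2p̂q̂ · n_alleles/(n_alleles − 1) (unbiased); π equals unbiased per-site
heterozygosity at a bi-allelic site.  Population values are averages
over variant sites, or sums divided by total sequenced length in
"all-positions" mode (variant-only values therefore dominate
all-positions values).  F_IS = 1 − H̄_O/H̄_E as a ratio of averages
(stacks convention — per-locus-ratio averaging gives different numbers);
0/0 is reported as missing.  Individual heterozygosity is the
heterozygous fraction of each individual's non-missing SNP calls.

KING-robust kinship: φ̂_ij = (N_Aa,Aa − 2N_AA,aa)/(N_Aa(i) + N_Aa(j))
over the pair's overlapping calls; self-pairs give 0.5 for non-inbred
individuals, unrelated pairs scatter around 0 (negative values are a
normal estimator property).  Pairs with fewer than 100 overlapping SNPs
(configurable) are reported but excluded from unrelated-set selection.
Unrelated-set selection greedily deletes, within each connected
component of the φ > threshold graph, the individual with the most
missing data (ties by id order) until no edge remains — so among
relatives the most complete individual is kept.  The function's default
threshold is strictly 0 (the study's rule); the pipeline default is
0.044, the standard third-degree cutoff, because with a finite SNP panel
φ̂ of truly unrelated pairs is symmetric noise around zero and a strict
> 0 rule flags about half of all pairs (the rule behaved on the real
data because inbreeding and substructure biased unrelated φ̂ negative).

Weir–Cockerham F_ST sums the a (among), b (between individuals within)
and c (within-individual) variance components over loci,
F = Σa/Σ(a+b+c).  Significance is a label permutation test (group sizes
preserved, vectorised over permutations) with the add-one convention
p = (1 + #{F_perm ≥ F_obs})/(1 + B), which can never return exactly 0
and is exactly calibrated at nominal levels of the form k/(B+1).  The
study text attributes its F_ST significance to "Fisher's exact tests
after 10,000 permutations", which is internally contradictory; a
permutation null is what is implemented here.

## mtDNA statistics

Distances between sequences are nucleotide differences with N/-
excluded pairwise (not column-wise); haplotype collapsing treats N as a
mismatch by default (museum-grade conservatism) with an optional
wildcard mode.  Hd = n(1 − Σp_i²)/(n − 1) with Nei's sampling variance
so Welch-style comparisons are possible downstream.  Tajima's D uses
the standard a/b/c/e coefficients (negative = rare-variant excess,
expansion; positive = contraction/structure) and is an explicit error at
S = 0.  Phi_ST is the two-level AMOVA ratio σ_a/(σ_a+σ_w) on squared
distances; with all haplotypes equidistant it reduces to frequency-based
F_ST.  The three-level AMOVA (groups / populations within groups /
within populations) uses the classical unbalanced-design coefficients;
percentages may be negative and sum to 100; the no-replication case (one
population per group) reports the middle component as exactly 0.
Permutation schemes per level: whole populations across groups (Phi_CT),
individuals across populations within their group (Phi_SC), individuals
across everything (Phi_ST); defaults 10 000 permutations (tests use
999).

The network builder connects haplotypes level-by-level in increasing
mutational distance: a pair is linked only if its endpoints were in
different components before that distance level began (shorter
connections exhaust longer alternatives), all equal-length alternatives
are kept (cycles allowed), and multi-step links insert inferred
intermediate nodes.  The auto connection limit is the largest j for
which the probability that all j observed differences are single-step
changes — (λe^{−λ}/(1−e^{−λ}))^j with λ the Jukes–Cantor-corrected
per-site intensity at j/L — stays ≥ 0.95.  This is a deliberately
compact stand-in for the full statistical-parsimony recursion (adequate
for small, well-resolved networks); a fixed limit can always be passed
explicitly.

## Numerical choices and degenerate inputs

* Zero-duration epochs in the analytic SFS are collapsed with a warning.
* Monomorphic datasets: F_ST and Phi_ST raise (undefined) rather than
  return 0; Tajima's D raises at S = 0.
* All stochastic operations derive from a single integer seed per entry
  point; reruns are bit-identical (tested), and internal seeds stay
  below 2³¹.
* Every shipped experiment's problem size (loci counts, replicate and
  permutation counts, genealogy counts) is stated at its call site;
  they are the package's chosen scales for its own test battery.

## Known limitations

Heavy migration/size combinations make the event-driven kernel slow
(mitigated by the event cap); the composite likelihood ignores linkage
within loci (one SNP per locus is the mitigation, as in the source
protocol); Monte-Carlo lnL noise means nested-model lnL ordering holds
only up to a tolerance; the TCS limit approximation is conservative on
short fragments; and the pipeline's kinship threshold choice trades the
study's literal rule for statistical sanity on panels without inbreeding
(both behaviours available).
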