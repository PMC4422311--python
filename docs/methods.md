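# Methods

This note documents the models, parameter choices and numerical decisions
behind lineagekit, and what the synthetic-data tests do and do not
demonstrate about real data.

## Variant nomenclature and exclusions

Variants are rCRS-relative tokens on a 1-based, closed-coordinate, circular
16,569-bp frame; a covered range may wrap through the origin (the control
region is conventionally reported as 16024–576). Identity of a variant is
`(position, kind, alt, back-mutation flag)`: the reference base is context
(so `16223T` read against a reference whose base 16223 is C equals
`C16223T`), annotation suffixes are opaque metadata, and insertion run
lengths are ignored (`573.XC` ≡ `573.1C`) because mtDNA length polymorphism
is not phylogenetically informative at this scale. IUPAC ambiguity codes
are parsed as point heteroplasmies and dropped by the default filter.

The default hypervariable exclusion set is exactly {A16182C, A16183C,
T16519C} plus the 309–315 length-variation window around position 310 and
point heteroplasmies — the standard pre-filter before network building,
classification and dating. Nothing else is removed.

The packaged full-length reference generator is synthetic (a seeded uniform
ACGT sequence): it provides a coordinate frame for tests without embedding
the real rCRS, which users should supply as FASTA for real-data work. This
affects nothing downstream, since all computations are on variant tokens or
user-provided alignments.

## Haplogroup classification

The classifier scores every tree node as the fraction of its range-
restricted cumulative motif observed in the haplotype, minus 0.01 per
private variant, floored at zero. The penalty constant is deliberately
small: it orders otherwise-tied nodes without letting private variation
overturn genuine motif matches. Nodes with no scorable variant in range
inherit the parent's fraction but can never outrank the node they inherit
from; evidence-backed ties resolve toward the deeper node, then
lexicographically, making results independent of input order. This scoring
is intentionally transparent rather than a re-implementation of any
published tool's proprietary weighting; on haplotypes that actually carry a
node's motif it is exact (score 1.0, empty private set).

Back mutations in motifs cancel the matching ancestral-path variant. A
reversion with no earlier match is kept in the motif as-is; since an
rCRS-relative variant list cannot express "matches the reference", such a
variant counts as missing — a conservative, deterministic convention.

Y-SNP profiles are resolved on a one-marker-per-branch hierarchy. Untested
markers are skipped, never assumed ancestral; a derived call below a tested
ancestral ancestor raises an error naming the conflict. Partially resolved
assignments render with the exclusion notation (`Q*(×Q1a3a1)`), compressing
contiguous single-letter sibling suffixes (`Q1a3a1a-c`).

## Median-joining networks

Haplotypes are condensed to a character matrix (identical haplotypes
collapse with summed multiplicity and per-group counts; invariant sites are
dropped but remain traceable to rCRS coordinates). The network construction
iterates: (i) the ε-relaxed minimum spanning network, where a pair is
linked iff its distance is within ε of the minimax (bottleneck) path cost —
at ε = 0 this is the union of all minimum spanning trees; (ii) median
(Steiner) vector generation for triples with at least two links, adding
per-site majority consensus vectors whose connection cost is within ε of
the minimum; (iii) on convergence, pruning of inferred medians whose
removal does not lengthen the minimum spanning structure. ε defaults to 0
and is exposed as a parameter. Determinism comes from canonical sorting of
input haplotypes and naming medians `mvN` in creation order.

`total_length` is the minimum-spanning-tree length over the final node set.
An exact Dreyfus–Wagner Steiner-tree solver over the site-state product
graph serves as an independent reference on small inputs; the bundled toys
(≤ 5 haplotypes, ≤ 8 sites) all attain the exact Steiner minimum. This
exactness is verified only at desk scale — median joining carries no global
optimality guarantee on large multistate data.

## Parsimony

Weighted Fitch lengths are computed on nested-tuple topologies (score
invariant to rooting). `mp_search` enumerates all (2n−5)!! unrooted
topologies up to a 9-taxon bound and returns every minimum-length tree; an
optional constraint restricts the search to topologies where named groups
(e.g. haplogroup assignments) are monophyletic, the practical mode for
anything larger.

## Clade dating

rho = (1/n) Σ m_i n_i (equivalently the mean tip-to-root mutation count),
with the heuristic genealogy-based error σ² = Σ (n_i/n)² m_i. The
star-likeness index is read as ρ/(n·σ²) — the grouping is fixed by its
stated bounds, 1 for a perfect star (n tips, one private mutation each:
ρ = 1, σ² = 1/n) and 1/n for a single shared haplotype (one branch with
m mutations above all n tips: ρ = m, σ² = m). A mutation-free clade has an
undefined index, reported as missing. Method concordance reports per-clade
rho/ML age ratios and flags ratios above a configurable threshold (default
1.5) as non-star-likeness warnings, the regime where rho dating is known to
misbehave.

### Clock maximum likelihood

The ML distance maximises an HKY85 likelihood with discrete-gamma rate
variation (default 32 equal-probability categories, mean-of-bin rates)
under a strict clock on a fixed rooted topology, with partition-specific
rate multipliers for HVS-I (16051–16400), HVS-II (68–263) and the remainder,
constrained to a site-weighted mean of 1 so the root height is on the
molecule-average substitution scale. Node times are parameterised as a root
height plus per-node fractions of the parent time; optimisation is L-BFGS-B
followed by a Nelder–Mead polish from fixed starting points (root height
from half the mean pairwise mismatch, fractions 0.5, κ = 2, α = 0.5),
tolerance 1e-6 in log-likelihood. κ and α are clamped to [0.01, 1000] and
[0.01, 100]; beyond these the likelihood is numerically flat. Base
frequencies default to the empirical alignment composition (with a
pseudocount if a base is absent). The transition matrix uses the analytic
symmetrised eigendecomposition of the reversible HKY generator, verified
against `expm` in the tests; the two-taxon κ = 1/equal-frequency limit
agrees with the closed-form distance to ~1e-9, and a five-tip optimum
matches an independent grid search to 3 decimals. Gaps and ambiguity codes
contribute a flat partial likelihood (missing data).

### Corrected molecular clock

Ages come from inverting a monotone expected-distance curve

    d(T) = T / τ_L + (τ_S / τ_X)(1 − exp(−T / τ_S))

with τ_L = 3,624 years per whole-molecule substitution (the accepted
long-term rate), an excess-mutation scale τ_X = 8,800 years and a purging
timescale τ_S = 45,000 years. The structure expresses purifying selection:
mildly deleterious variants accumulate at a higher short-term rate and are
removed over time, so young clades look "faster" (≈ 2.56 kyr per mutation)
than old ones (≈ 2.66 kyr per mutation over the Holocene range). The two
free constants were fixed once against published whole-mtDNA clade
(distance, age) pairs, which they reproduce within 0.7% across 1.3–12.2 kya;
they are calibration constants of the package, not tuned per analysis.
Confidence intervals are formed on the mutation scale (max(0, d − 1.96σ),
d + 1.96σ) and then converted — this, not time-scale symmetry, is what
yields the asymmetric printed intervals. Inversion is by bracketed root
finding (domain 0–2 Myr); `clock_convert` is strictly increasing with an
exact round trip through `expected_distance`.

A `synonymous` mode applies a plain linear clock at one synonymous
substitution per 7,884 years; a `linear` mode applies the long-term rate
with no transient excess and is the matching converter for the synthetic
clades, which are generated by a constant-rate neutral process (see below).

## Admixture and PCA

The admixture model is the standard unlinked binomial likelihood; fitting
alternates exact EM updates in Q and P, which are monotone in log-likelihood
(asserted in tests on every run). Convergence: tolerance 1e-6 log-likelihood
units, max 2,000 iterations, fixed seeds. Allele frequencies are kept in
[1e-6, 1 − 1e-6] during optimisation. Missing genotypes contribute nothing
to the likelihood; monomorphic markers are excluded with a warning.
Supervised mode pins reference rows to one-hot ancestry; the default
unsupervised mode (references and study individuals fitted jointly) uses
references only for initialisation and component labelling, via Hungarian
assignment of components to the reference group with highest mean
membership. K is chosen by masked-entry cross-validation (random entry
folds fixed once per seed; prediction error on held-out dosages against
2 Σ q p). PCA mean-imputes missing entries per marker, centres columns, and
fixes each component's sign so its largest-magnitude loading is positive.

A caveat documented by the simulations: with only ~46 biallelic markers at
continental-scale divergence (Fst ≈ 0.15), per-individual ancestry
estimates carry an irreducible error of roughly ±0.12 per component — the
known-truth maximum-likelihood bound, not an implementation artefact — and
unsupervised fits shrink one-hot reference individuals visibly toward the
interior. Group means over ~100 individuals are recovered to within ~0.02.
Conclusions from such panels should rest on group-level summaries, which is
how the pipeline reports them.

## Synthetic data

`sim_clade` draws a star or Kingman-coalescent genealogy, rescales the
coalescent so the realised root time equals the requested TMRCA
(conditioning, so truth is known exactly), and lays mutations down as a
Poisson process at a whole-molecule rate (default test setting: 1/3,624 per
year) placed multinomially over sites; hits toggle a site between
transition partners, so recurrent mutation and reversion arise naturally at
high rates. It emits aligned sequences, a presence/absence matrix and the
true branch summary, whose branch sums equal the per-tip root distances by
construction. `sim_reference_freqs` draws Balding–Nichols population
frequencies (Beta around a shared ancestral frequency, default ancestral
range U(0.1, 0.9), Fst 0.15, 46 markers); `sim_admixed_genotypes` adds
one-hot reference individuals at the 105/158/64 three-continent panel sizes
and study genotypes from Binomial(2, Σ q p) with Dirichlet(1) or fixed
ancestry. `sim_tree_haplotypes` emits each (distinguishable) node's full
motif plus Poisson private variants at positions no motif uses. Every
generator is a pure function of its spec including the seed.

What the synthetic tests do not emulate: sequencing error, heteroplasmy,
rate heterogeneity beyond site weights, linkage between AIMs, reference
panel misspecification, and real AIM panels' deliberately extreme frequency
differentials. Passing recovery tests therefore demonstrates correctness of
the estimators under their own model assumptions, not field performance.

## Problem sizes in the default test run

The bundled suite runs 200 star-clade replicates (n = 20 tips, 1,000 sites)
for rho recovery, 500 random coalescent genealogies for the star-index
bound, five 5-taxon matrices for the parsimony oracle, the six network
toys, and one 427-individual × 46-marker admixture study — sizes chosen to
give stable statistics on a single CPU in well under a minute per property.

## Known limitations

- Median-joining here targets desk-scale control-region data; no reduced-
  median preprocessing, and no claim of optimality beyond the verified toys.
- The ML dating optimiser is a general-purpose quasi-Newton scheme, not a
  specialised tree-peeling Newton iteration; it is intended for the small
  mitogenome clades this pipeline dates, not genome-scale alignments.
- The clock calibration is specific to human whole-mtDNA distances; other
  loci or species require refitting τ_L, τ_X, τ_S.
- Heteroplasmy handling stops at parse-and-drop; downstream weighting of
  ambiguous calls is not modelled.
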