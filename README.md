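# lineagekit

A toolkit for uniparental-marker phylogeography and ancestry analysis of
human population samples: mtDNA haplogroup classification, Y-SNP haplogroup
assignment, median-joining haplotype networks, clade dating (rho statistic
and clock-constrained maximum likelihood) with a purifying-selection-
corrected molecular clock, and continental-ancestry estimation from small
panels of ancestry-informative markers (AIMs).

It is aimed at population and forensic geneticists who work with the classic
study design for under-sampled populations: control-region and whole-mtDNA
sequences referenced to the rCRS, a Y-SNP hierarchy typed with a small
marker multiplex, and a biallelic AIM-InDel panel typed in study individuals
alongside three-continent reference panels. Every analysis stage is paired
with a synthetic-data generator with known ground truth, so the whole
pipeline is testable without any external downloads.

## What it computes

**Haplogroup classification.** A haplogroup tree assigns each named clade a
set of defining variants in the standard rCRS-relative token grammar
(`T16362C`, `@T16362C` for a reversion, `573.XC` for a C-run insertion,
annotation suffixes `s`, `-t`, `-r`, `-nc`). The cumulative motif of a node
is the union of defining variants along the root path with back mutations
cancelling. A haplotype restricted to its sequenced range is scored against
every node by

    score(node) = |found| / |expected in range| − 0.01 · |private|,

with deterministic tie-breaking; Y profiles are resolved to the deepest
derived branch and rendered with exclusion notation, e.g.
`Q1a3a1*(×Q1a3a1a-c)`.

**Networks and parsimony.** Condensed haplotype matrices feed a
median-joining network construction (relaxed minimum spanning network plus
median/Steiner vectors within tolerance ε), an exact Steiner-tree reference
solver for desk-scale checks, weighted Fitch parsimony, and an exhaustive
maximum-parsimony search for small clades.

**Clade dating.** For a clade of *n* sampled sequences with genealogy
branches carrying *m<sub>i</sub>* mutations above *n<sub>i</sub>* tips:

    rho      = (1/n) Σ m_i n_i               (mean distance to the root)
    sigma²   = Σ (n_i / n)² m_i              (heuristic standard error)
    star     = rho / (n · sigma²)            (1 = perfect star, 1/n = one
                                              shared haplotype)

An independent estimate is the clock-constrained HKY85 + discrete-gamma
(32 categories) maximum-likelihood root-to-tip distance with partition-
specific rates for HVS-I (16051–16400), HVS-II (68–263) and the remainder
of the molecule. Mutational distances *d* convert to years through a
time-dependent clock that models purifying selection — young clades carry a
transient excess of mildly deleterious variants:

    d(T) = T/3624 + (τ_s/8800) · (1 − exp(−T/τ_s)),   τ_s = 45,000 yr

inverted numerically, with confidence intervals formed on the mutation
scale (d ± 1.96σ) and then converted, which reproduces the characteristic
asymmetric CIs of whole-mtDNA dating tables.

**Ancestry.** Per-individual ancestry fractions under the binomial
admixture likelihood Π<sub>il</sub> Binom(g<sub>il</sub>; 2,
Σ<sub>k</sub> q<sub>ik</sub> p<sub>kl</sub>), fitted by monotone EM updates
in Q and P, supervised or unsupervised with continental reference panels;
masked-entry cross-validation for choosing K; PCA of the centered dosage
matrix.

## Worked example

```python
import lineagekit as lk
from lineagekit import chronos, haplotree, mtio

tree = lk.load_demo_tree()
rec = mtio.HaplotypeRecord(
    "GT-Qeqchi-01", "Maya", "Q'eqchi'", [(16024, 576)],
    [mtio.parse_variant(t) for t in
     ["C64T", "C146T", "A153G", "A235G", "C16111T", "C16290T",
      "G16319A", "T16362C", "T16092C"]])
res = haplotree.classify_mtdna(rec, tree)
print(res.best, res.score)            # A2+T16092C 1.0

clade = chronos.CladeSummary(n=4, branches=[
    chronos.GenealogyBranch(2, 4), chronos.GenealogyBranch(1, 2),
    chronos.GenealogyBranch(0, 1), chronos.GenealogyBranch(1, 1),
    chronos.GenealogyBranch(0, 1), chronos.GenealogyBranch(1, 1)])
print(chronos.rho_stat(clade))        # 3.0
r = chronos.date_clade_rho(clade, name="B2t-like")
print(f"{r.age_years/1000:.2f} kya")  # 7.89 kya
print(lk.clock_convert(2.23))         # 5830.4... (~5.83 kya)
```

The classification says the haplotype carries the full A2 motif plus
T16092C, landing on the A2+T16092C sub-clade with a perfect score; the toy
four-genome clade has a mean root distance of 3 mutations, dating to about
7.9 kya under the corrected clock; and a whole-mtDNA ML distance of 2.23
mutations converts to roughly 5.8 kya.

A command-line pipeline wraps the same stages:

```
lineagekit simulate --config run.cfg     # deterministic synthetic fixtures
lineagekit pipeline --config run.cfg     # classify, network, date, admix
lineagekit show-config                   # effective defaults
```

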