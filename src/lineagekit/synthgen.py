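"""Synthetic inputs with known truth for every analysis stage.

Three families of generators mirror the statistical structure the pipeline
assumes: (i) clades of mtDNA sequences descending from a known root at a
known TMRCA, with mutations laid down as a Poisson process along a star or
Kingman-coalescent genealogy (the coalescent is rescaled so the realised
root time equals the requested TMRCA — truth is conditioned, not random);
(ii) continental reference panels plus admixed study individuals on
biallelic markers, with allele frequencies drawn from the Balding-Nichols
Beta model around shared ancestral frequencies and genotypes from the
binomial admixture model; and (iii) haplotypes walked down a haplogroup
tree, carrying each node's full motif plus Poisson-distributed private
variants, for classifier tests.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ancestry import GenotypeMatrix, ReferencePanel
from .chronos import CladeSummary, GenealogyBranch
from .haplotree import HaploTree, expected_motif
from .mtio import (RCRS_LENGTH, HaplotypeRecord, MtVariant, SequenceRecord,
                   TRANSITION_PARTNER, synthetic_reference)
from .netforge import CharacterMatrix

DEFAULT_REF_SIZES = (105, 158, 64)


# --------------------------------------------------------------------------
# Clade simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSimSpec:
    n_tips: int
    tmrca_years: float
    rate_per_year: float                  # whole-molecule mutation rate
    genealogy: str = "star"               # or 'kingman_coalescent'
    n_sites: int = 1000
    site_weights: Optional[Sequence[float]] = None
    root_sequence: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 1 or self.rate_per_year < 0 or self.tmrca_years < 0:
            raise ValueError("invalid clade simulation spec")
        if self.genealogy not in ("star", "kingman_coalescent"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")


@dataclass
class CladeSim:
    sequences: list                      # SequenceRecord per tip + root
    matrix: CharacterMatrix
    summary: CladeSummary
    tmrca_years: float
    tip_mutations: list                  # per-tip root distances


def _kingman_times(n, rng):
    """Coalescent node times (standard scale), tips at 0, root last."""
    times, t = [], 0.0
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        times.append(t)
    return times


def sim_clade(spec: CladeSimSpec) -> CladeSim:
    """Simulate sequences down a clade genealogy of known TMRCA.

    Mutations are Poisson along each branch at ``rate_per_year`` (whole
    molecule), placed multinomially over sites by weight; each hit toggles
    the site to the transition partner of its current state (recurrent hits
    can revert).  Returns the sequences, the condensed presence/absence
    matrix relative to the root, and the true branch summary.
    """
    rng = np.random.default_rng(spec.seed)
    root = spec.root_sequence or synthetic_reference(
        seed=spec.seed + 1, length=spec.n_sites)
    n_sites = len(root)
    weights = np.asarray(spec.site_weights
                         if spec.site_weights is not None
                         else np.ones(n_sites), float)
    weights = weights / weights.sum()

    # genealogy: list of branches (parent_time, child_time, tips below)
    branches = []
    if spec.genealogy == "star":
        for i in range(spec.n_tips):
            branches.append((spec.tmrca_years, 0.0, (i,)))
    else:
        raw = _kingman_times(spec.n_tips, rng)
        if spec.n_tips > 1:
            scale = spec.tmrca_years / raw[-1]  # condition on the TMRCA
            times = [t * scale for t in raw]
        else:
            times = []
        # build topology by random merging, tracking tip sets
        nodes = [{"time": 0.0, "tips": (i,)} for i in range(spec.n_tips)]
        active = list(range(spec.n_tips))
        for t in times:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            a, b = active[i], active[j]
            new = {"time": t, "tips": tuple(sorted(nodes[a]["tips"]
                                                   + nodes[b]["tips"]))}
            nodes.append(new)
            nid = len(nodes) - 1
            for child in (a, b):
                branches.append((t, nodes[child]["time"],
                                 nodes[child]["tips"]))
            active = [x for k, x in enumerate(active) if k not in (i, j)]
            active.append(nid)

    # mutations per branch
    seq_arr = np.array(list(root))
    tip_seqs = [seq_arr.copy() for _ in range(spec.n_tips)]
    summary_branches = []
    tip_mut = [0] * spec.n_tips
    for p_t, c_t, tips in sorted(branches,
                                 key=lambda br: (-br[0], br[2])):
        m = rng.poisson(spec.rate_per_year * (p_t - c_t))
        sites = rng.choice(n_sites, size=m, p=weights)
        summary_branches.append(GenealogyBranch(int(m), len(tips)))
        for t in tips:
            tip_mut[t] += int(m)
        for s in sites:
            for t in tips:
                tip_seqs[t][s] = TRANSITION_PARTNER[tip_seqs[t][s]]

    records = [SequenceRecord(f"tip{i}", "".join(s))
               for i, s in enumerate(tip_seqs)]
    records.append(SequenceRecord("root", root))

    # presence/absence matrix relative to root (variant sites only)
    diffs = np.array([s != seq_arr for s in tip_seqs], dtype=object)
    var_sites = [j for j in range(n_sites)
                 if any(diffs[i, j] for i in range(spec.n_tips))]
    states = np.array([[1 if tip_seqs[i][j] != seq_arr[j] else 0
                        for j in var_sites]
                       for i in range(spec.n_tips)], dtype=object)
    if states.size == 0:
        states = states.reshape(spec.n_tips, 0)
    matrix = CharacterMatrix(
        taxa=[f"tip{i}" for i in range(spec.n_tips)],
        states=states, positions=[j + 1 for j in var_sites])

    summary = CladeSummary(n=spec.n_tips, branches=summary_branches)
    return CladeSim(sequences=records, matrix=matrix, summary=summary,
                    tmrca_years=spec.tmrca_years, tip_mutations=tip_mut)


# --------------------------------------------------------------------------
# Admixture simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdmixSimSpec:
    K: int = 3
    n_markers: int = 46
    fst: float = 0.15
    ancestral_freq_range: tuple = (0.1, 0.9)
    q_mode: str = "dirichlet"             # or 'fixed'
    q_fixed: Optional[Sequence[float]] = None
    dirichlet_alpha: float = 1.0
    n_study: int = 100
    ref_sizes: Sequence[int] = DEFAULT_REF_SIZES
    ref_labels: Sequence[str] = ("AFR", "EUR", "AME")
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if len(self.ref_sizes) != self.K:
            raise ValueError("ref_sizes length must equal K")


def sim_reference_freqs(spec: AdmixSimSpec) -> np.ndarray:
    """Balding-Nichols population frequencies, K x markers.

    Each population frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around a
    shared ancestral frequency p drawn uniformly from
    ``ancestral_freq_range``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_freq_range
    anc = rng.uniform(lo, hi, size=spec.n_markers)
    F = spec.fst
    a = anc * (1 - F) / F
    b = (1 - anc) * (1 - F) / F
    P = rng.beta(a, b, size=(spec.K, spec.n_markers))
    return np.clip(P, 1e-6, 1 - 1e-6)


def sim_admixed_genotypes(P: np.ndarray, spec: AdmixSimSpec):
    """Reference + study genotypes with known ancestry fractions.

    Reference individuals are one-hot in their own population; study
    individuals draw q from Dirichlet(alpha) (or use the fixed vector) and
    genotypes from Binomial(2, sum_k q_k p_kl).  Returns (GenotypeMatrix,
    true Q for all rows, ReferencePanel view).
    """
    P = np.asarray(P, float)
    if P.shape != (spec.K, spec.n_markers):
        raise ValueError("P dimensions do not match spec")
    rng = np.random.default_rng(spec.seed + 1)
    individuals, labels, qs = [], [], []
    for k, (size, lab) in enumerate(zip(spec.ref_sizes, spec.ref_labels)):
        for i in range(size):
            individuals.append(f"{lab}_{i:03d}")
            labels.append(lab)
            q = np.zeros(spec.K)
            q[k] = 1.0
            qs.append(q)
    for i in range(spec.n_study):
        individuals.append(f"study_{i:03d}")
        labels.append("study")
        if spec.q_mode == "fixed":
            if spec.q_fixed is None:
                raise ValueError("q_mode='fixed' requires q_fixed")
            qs.append(np.asarray(spec.q_fixed, float))
        else:
            qs.append(rng.dirichlet([spec.dirichlet_alpha] * spec.K))
    Qtrue = np.vstack(qs)
    mu = Qtrue @ P
    dosage = rng.binomial(2, mu).astype(float)
    G = GenotypeMatrix(individuals, labels,
                       [f"m{j:02d}" for j in range(spec.n_markers)], dosage)
    n_ref = int(sum(spec.ref_sizes))
    panel = ReferencePanel(G.subset(range(n_ref)))
    return G, Qtrue, panel


# --------------------------------------------------------------------------
# Haplotype simulation down a haplogroup tree
# --------------------------------------------------------------------------

def sim_tree_haplotypes(tree: HaploTree, n_per_node: int = 1,
                        extra_private_mutations: float = 0.0,
                        seed: int = 0,
                        covered_range=((1, RCRS_LENGTH),),
                        nodes: Optional[Sequence[str]] = None
                        ) -> list[HaplotypeRecord]:
    """Haplotypes carrying each node's full motif plus private noise.

    Private variants are Poisson(``extra_private_mutations``) transitions at
    positions used by no motif in the tree, so they never collide with a
    defining variant.  The true node name is recorded in
    ``assigned_haplogroup``.  By default only distinguishable nodes are
    sampled: a node whose cumulative motif equals its parent's (a structural
    placeholder) cannot be recovered from variants and is skipped.
    """
    rng = np.random.default_rng(seed)
    if nodes is not None:
        names = list(nodes)
    else:
        names = [n for n in sorted(tree.nodes)
                 if tree.nodes[n].parent is None
                 or expected_motif(tree, n)
                 != expected_motif(tree, tree.nodes[n].parent)]
    used_positions = {v.position for n in tree.nodes
                      for v in expected_motif(tree, n)}
    free_positions = [p for p in range(30, 16400)
                      if p not in used_positions and not 309 <= p <= 315
                      and p not in (16182, 16183, 16519)]
    records = []
    for name in names:
        motif = sorted(expected_motif(tree, name),
                       key=lambda v: (v.position, str(v.alt)))
        motif = [v for v in motif if not v.is_back_mutation]
        for i in range(n_per_node):
            k = rng.poisson(extra_private_mutations)
            extra_pos = rng.choice(len(free_positions), size=k,
                                   replace=False)
            extras = []
            for idx in sorted(extra_pos):
                p = free_positions[idx]
                ref = rng.choice(list("ACGT"))
                extras.append(MtVariant(int(p), "sub", ref_base=str(ref),
                                        alt=TRANSITION_PARTNER[str(ref)]))
            records.append(HaplotypeRecord(
                sample_id=f"{name}_{i}",
                population="Maya",
                ethnic_group="synthetic",
                covered_range=list(covered_range),
                variants=list(motif) + extras,
                assigned_haplogroup=name,
            ))
    return records
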