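"""Continental ancestry estimation from biallelic ancestry-informative
markers (AIMs).

The model is the standard unlinked admixture likelihood: individual ``i``
has ancestry fractions ``q_i`` over K ancestral populations with allele
frequencies ``p_k``; the genotype dosage at marker ``l`` is
Binomial(2, sum_k q_ik p_kl).  The fit alternates the classic EM updates in
Q and P, which never decrease the log-likelihood; reference individuals with
known continental labels can either be fixed at one-hot ancestry
(supervised) or merely used to initialise and label components
(unsupervised, the default for a joint run with references included).  K is
chosen by masked-entry cross-validation, and principal-component projections
of the dosage matrix provide the accompanying ordination.

The study design this mirrors is a three-continent reference panel
(Africa/Europe/America, 105/158/64 individuals) plus study genotypes on a
46-marker insertion/deletion panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

EPS_P = 1e-6   # allele-frequency boundary during optimisation
EPS_Q = 1e-9

DEFAULT_REF_COMPOSITION = {"AFR": 105, "EUR": 158, "AME": 64}


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix (0/1/2, NaN = missing)."""

    individuals: list
    labels: list            # population tag per individual (AFR/EUR/AME/...)
    markers: list
    dosages: np.ndarray     # float array, NaN for missing

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def n(self):
        return len(self.individuals)

    @property
    def m(self):
        return len(self.markers)

    def subset(self, rows):
        rows = list(rows)
        return GenotypeMatrix(
            [self.individuals[i] for i in rows],
            [self.labels[i] for i in rows],
            list(self.markers), self.dosages[rows])


@dataclass
class ReferencePanel:
    """Reference rows with fixed continental labels."""

    genotypes: GenotypeMatrix
    composition: dict = field(default_factory=dict)

    def __post_init__(self):
        counts: dict = {}
        for lab in self.genotypes.labels:
            counts[lab] = counts.get(lab, 0) + 1
        if not self.composition:
            self.composition = counts
        elif counts != self.composition:
            raise ValueError(
                f"label counts {counts} do not match declared composition "
                f"{self.composition}")


def read_genotype_table(path_or_buf) -> GenotypeMatrix:
    """TSV: individual, group, then one 0/1/2/NA column per marker."""
    close = isinstance(path_or_buf, str)
    fh = open(path_or_buf) if close else path_or_buf
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["individual", "group"]:
            raise ValueError("first columns must be 'individual', 'group'")
        markers = header[2:]
        individuals, labels, rows = [], [], []
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            individuals.append(cells[0])
            labels.append(cells[1])
            rows.append([np.nan if c in ("NA", "") else float(c)
                         for c in cells[2:]])
        return GenotypeMatrix(individuals, labels, markers,
                              np.asarray(rows, float))
    finally:
        if close:
            fh.close()


def write_genotype_table(g: GenotypeMatrix, path_or_buf):
    close = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w") if close else path_or_buf
    try:
        fh.write("individual\tgroup\t" + "\t".join(g.markers) + "\n")
        for i in range(g.n):
            cells = ["NA" if np.isnan(d) else str(int(d))
                     for d in g.dosages[i]]
            fh.write(f"{g.individuals[i]}\t{g.labels[i]}\t"
                     + "\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def read_genotype_vcf(path, group_map: Optional[dict] = None
                      ) -> GenotypeMatrix:
    """Read biallelic indel/SNP genotypes from a VCF (GT field -> dosage).

    Dosage counts copies of the first ALT allele.  Calls involving any
    other allele index (multi-allelic records, e.g. a rare third allelic
    state at an indel locus) are recorded as missing, since a biallelic
    dosage model has no slot for them.  ``group_map`` assigns population
    labels per sample id (default ``study``).
    """
    from cyvcf2 import VCF

    v = VCF(path)
    samples = list(v.samples)
    markers, rows = [], []
    for var in v:
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        dos = []
        for g in var.genotypes:
            alleles = [a for a in g[:-1]]
            if any(a not in (0, 1) for a in alleles):
                dos.append(np.nan)  # missing or non-primary allele
            else:
                dos.append(float(sum(alleles)))
        rows.append(dos)
    dosages = np.asarray(rows, float).T if rows else \
        np.zeros((len(samples), 0))
    labels = [(group_map or {}).get(s, "study") for s in samples]
    return GenotypeMatrix(samples, labels, markers, dosages)


# --------------------------------------------------------------------------
# Admixture fit
# --------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    Q: np.ndarray                # individuals x K
    P: np.ndarray                # K x markers
    log_likelihood_trace: list
    component_labels: list       # component -> reference label (or 'K<i>')
    kept_markers: list           # indices of polymorphic markers used


def _loglik(G, Q, P):
    mu = Q @ P
    with np.errstate(invalid="ignore"):
        ll = G * np.log(mu) + (2.0 - G) * np.log(1.0 - mu)
    return float(np.nansum(ll))


def admixture_fit(G: GenotypeMatrix, K: int,
                  refs: Optional[ReferencePanel] = None,
                  supervised: bool = False,
                  tol: float = 1e-6, max_iter: int = 2000,
                  seed: int = 0) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by alternating EM updates.

    ``refs`` rows are matched to ``G`` rows by individual id.  In supervised
    mode their Q rows are pinned one-hot to their continental label; in the
    default unsupervised mode they only initialise (and afterwards label)
    the components.  Missing genotypes contribute nothing to the
    likelihood; markers monomorphic across all data are excluded with a
    warning.  The log-likelihood trace is non-decreasing.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    X = G.dosages.copy()

    poly = [j for j in range(G.m)
            if np.nanstd(X[:, j]) > 0]
    if len(poly) < G.m:
        warnings.warn(f"excluding {G.m - len(poly)} monomorphic markers")
    X = X[:, poly]
    n, m = X.shape

    ref_rows: dict[int, int] = {}   # row in G -> component index
    label_of_component: dict[int, str] = {}
    if refs is not None:
        ref_labels = sorted(set(refs.genotypes.labels))
        if supervised and K > len(ref_labels):
            raise ValueError(
                f"supervised mode needs K <= {len(ref_labels)} reference "
                "labels")
        comp_of_label = {lab: k for k, lab in enumerate(ref_labels[:K])}
        by_id = {ind: lab for ind, lab in
                 zip(refs.genotypes.individuals, refs.genotypes.labels)}
        for i, ind in enumerate(G.individuals):
            lab = by_id.get(ind)
            if lab in comp_of_label:
                ref_rows[i] = comp_of_label[lab]
        label_of_component = {k: lab for lab, k in comp_of_label.items()}

    # initialisation: references one-hot-ish, others uniform + jitter
    Q = np.full((n, K), 1.0 / K)
    Q += rng.uniform(-0.01, 0.01, size=Q.shape) / K
    Q = np.clip(Q, EPS_Q, None)
    Q /= Q.sum(axis=1, keepdims=True)
    for i, k in ref_rows.items():
        Q[i] = EPS_Q
        Q[i, k] = 1.0 - EPS_Q * (K - 1)
    P = np.clip(rng.uniform(0.2, 0.8, size=(K, m)), EPS_P, 1 - EPS_P)
    for k in range(K):
        members = [i for i, kk in ref_rows.items() if kk == k]
        if members:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                freq = np.nanmean(X[members], axis=0) / 2.0
            freq = np.where(np.isnan(freq), 0.5, freq)
            P[k] = np.clip(freq, EPS_P, 1 - EPS_P)

    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)

    trace = [_loglik(X, Q, P)]
    for _ in range(max_iter):
        mu = np.clip(Q @ P, 1e-12, 1 - 1e-12)
        # responsibilities: a = E[# derived copies from k], b = ancestral
        A = (Xf / mu)[:, None, :] * Q[:, :, None] * P[None, :, :]
        B = (((2.0 - Xf) * obs) / (1.0 - mu))[:, None, :] \
            * Q[:, :, None] * (1.0 - P)[None, :, :]
        A *= obs[:, None, :]
        # Q update
        Qnew = (A + B).sum(axis=2)
        denom = 2.0 * obs.sum(axis=1, keepdims=True)
        Qnew = np.where(denom > 0, Qnew / denom, 1.0 / K)
        Qnew = np.clip(Qnew, EPS_Q, None)
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        for i, k in ref_rows.items():
            if supervised:
                Qnew[i] = EPS_Q
                Qnew[i, k] = 1.0 - EPS_Q * (K - 1)
        # P update
        num = A.sum(axis=0)
        den = (A + B).sum(axis=0)
        Pnew = np.where(den > 0, num / np.clip(den, 1e-300, None), P)
        Pnew = np.clip(Pnew, EPS_P, 1 - EPS_P)

        Q, P = Qnew, Pnew
        trace.append(_loglik(X, Q, P))
        if abs(trace[-1] - trace[-2]) < tol:
            break

    # component labelling: Hungarian match on mean reference membership
    labels = [f"K{k}" for k in range(K)]
    if refs is not None and ref_rows:
        ref_label_list = sorted({label_of_component[k]
                                 for k in set(ref_rows.values())})
        score = np.zeros((len(ref_label_list), K))
        for li, lab in enumerate(ref_label_list):
            members = [i for i, k in ref_rows.items()
                       if label_of_component[k] == lab]
            score[li] = Q[members].mean(axis=0)
        rows, cols = linear_sum_assignment(-score)
        for li, k in zip(rows, cols):
            labels[k] = ref_label_list[li]

    return AdmixtureFit(Q=Q, P=P, log_likelihood_trace=trace,
                        component_labels=labels, kept_markers=poly)


def summarize_ancestry(Q: np.ndarray, group_labels: Sequence[str],
                       groups: Optional[Sequence[str]] = None):
    """Per-group mean ancestry fractions (rows sum to 1)."""
    if len(group_labels) != len(Q):
        raise ValueError("one group label per Q row required")
    if groups is None:
        groups = sorted(set(group_labels))
    else:
        unknown = set(group_labels) - set(groups)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
    arr = np.asarray(group_labels)
    return {g: np.asarray(Q)[arr == g].mean(axis=0) for g in groups}


def choose_k(G: GenotypeMatrix, refs: Optional[ReferencePanel],
             k_range: Sequence[int], folds: int = 5, seed: int = 0,
             tol: float = 1e-5, max_iter: int = 300):
    """Masked-entry cross-validation error per K.

    A random partition of the observed genotype entries into folds is fixed
    once; for each fold and K, the fold's entries are masked, the model is
    refit, and the squared error between the held-out dosage and its fitted
    expectation 2 sum_k q_ik p_kl is averaged.  Returns (errors dict,
    argmin K).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(~np.isnan(G.dosages))
    fold_of = rng.integers(0, folds, size=len(obs_idx))
    errors = {}
    for K in k_range:
        if K == 1:
            # no admixture structure: per-marker mean frequency
            err = []
            for f in range(folds):
                mask = obs_idx[fold_of == f]
                X = G.dosages.copy()
                X[mask[:, 0], mask[:, 1]] = np.nan
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mu = np.nanmean(X, axis=0)
                mu = np.where(np.isnan(mu), 1.0, mu)
                pred = mu[mask[:, 1]]
                err.append(np.mean(
                    (G.dosages[mask[:, 0], mask[:, 1]] - pred) ** 2))
            errors[K] = float(np.mean(err))
            continue
        err = []
        for f in range(folds):
            mask = obs_idx[fold_of == f]
            X = G.dosages.copy()
            X[mask[:, 0], mask[:, 1]] = np.nan
            Gm = GenotypeMatrix(G.individuals, G.labels, G.markers, X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = admixture_fit(Gm, K, refs=refs, tol=tol,
                                    max_iter=max_iter, seed=seed + f)
            back = np.full(G.m, -1)
            for new_j, old_j in enumerate(fit.kept_markers):
                back[old_j] = new_j
            mu = 2.0 * fit.Q @ fit.P
            sq = []
            for i, j in mask:
                jj = back[j]
                pred = mu[i, jj] if jj >= 0 else 1.0
                sq.append((G.dosages[i, j] - pred) ** 2)
            err.append(np.mean(sq))
        errors[K] = float(np.mean(err))
    best = min(errors, key=lambda k: (errors[k], k))
    return errors, best


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    kept_markers: list


def pca_project(G: GenotypeMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the column-centered dosage matrix.

    Missing entries are mean-imputed per marker; all-missing markers are
    dropped with a warning.  The sign of each component is fixed so that
    its largest-magnitude loading is positive.
    """
    if G.n < 2:
        raise ValueError("PCA needs at least two individuals")
    X = G.dosages.copy()
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing "
                      "markers")
    keep = np.nonzero(~all_missing)[0]
    X = X[:, keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(S))
    var = S ** 2 / max(G.n - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    for c in range(n_components):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio[:n_components],
                     kept_markers=[G.markers[j] for j in keep])


# --------------------------------------------------------------------------
# Report writers
# --------------------------------------------------------------------------

def write_q_matrix(fit: AdmixtureFit, individuals, path_or_buf):
    close = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w") if close else path_or_buf
    try:
        fh.write("individual\t" + "\t".join(fit.component_labels) + "\n")
        for ind, row in zip(individuals, fit.Q):
            fh.write(ind + "\t" + "\t".join(f"{q:.6f}" for q in row) + "\n")
    finally:
        if close:
            fh.close()


def write_pca_scores(res: PcaResult, individuals, path_or_buf):
    close = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w") if close else path_or_buf
    try:
        k = res.scores.shape[1]
        fh.write("individual\t" + "\t".join(f"PC{c+1}" for c in range(k))
                 + "\n")
        for ind, row in zip(individuals, res.scores):
            fh.write(ind + "\t" + "\t".join(f"{s:.6f}" for s in row) + "\n")
    finally:
        if close:
            fh.close()
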