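"""Rooted haplogroup trees and haplotype classification.

A haplogroup tree assigns each named clade (node) a small set of defining
variants; the cumulative "motif" of a node is the union of defining variants
along the path from the root, with back mutations (``@``-prefixed) cancelling
the matching earlier state.  mtDNA haplotypes are classified by scoring every
node against the observed variant list restricted to the sequenced range;
Y-chromosome profiles are classified by walking a binary marker hierarchy
(each SNP marker tags exactly one branch; derived = on the branch, ancestral
= off it), rendering partially resolved assignments with the conventional
exclusion notation, e.g. ``Q1a3a1*(×Q1a3a1a-c)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .mtio import (HaplotypeRecord, HypervariableExclusionSet, MtVariant,
                   filter_hypervariable, format_variant, parse_variant,
                   position_in_range)


class TreeError(ValueError):
    pass


class IncompatibleCallsError(ValueError):
    """Derived call below a branch whose tested ancestor is ancestral."""


@dataclass
class HaploNode:
    name: str
    parent: Optional[str]
    defining_variants: list = field(default_factory=list)


class HaploTree:
    """A rooted haplogroup tree keyed by unique node names."""

    def __init__(self, nodes: Iterable[HaploNode]):
        self.nodes: dict[str, HaploNode] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise TreeError(f"duplicate node name {n.name!r}")
            self.nodes[n.name] = n
        roots = [n.name for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, got {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise TreeError(f"{n.name}: unknown parent {n.parent!r}")
                self.children[n.parent].append(n.name)
        # acyclicity check: every node must reach the root
        for name in self.nodes:
            self.depth(name)

    def depth(self, name: str) -> int:
        d, seen = 0, set()
        while self.nodes[name].parent is not None:
            if name in seen:
                raise TreeError(f"cycle through {name!r}")
            seen.add(name)
            name = self.nodes[name].parent
            d += 1
        return d

    def path_from_root(self, name: str) -> list[str]:
        path = []
        while name is not None:
            path.append(name)
            name = self.nodes[name].parent
        return path[::-1]

    def descendants(self, name: str) -> list[str]:
        out, stack = [], list(self.children[name])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    # -- serialization: TSV of (child, parent, space-separated variants) ----
    @classmethod
    def from_tsv(cls, path_or_buf, reference: Optional[str] = None
                 ) -> "HaploTree":
        close = isinstance(path_or_buf, str)
        fh = open(path_or_buf) if close else path_or_buf
        try:
            nodes = []
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cells = line.split("\t")
                name = cells[0]
                parent = cells[1] if len(cells) > 1 and cells[1] else None
                tokens = cells[2].split() if len(cells) > 2 else []
                nodes.append(HaploNode(
                    name, parent,
                    [parse_variant(t, reference) for t in tokens]))
            return cls(nodes)
        finally:
            if close:
                fh.close()

    def to_tsv(self, path_or_buf):
        close = isinstance(path_or_buf, str)
        fh = open(path_or_buf, "w") if close else path_or_buf
        try:
            for name in sorted(self.nodes, key=lambda n: (self.depth(n), n)):
                node = self.nodes[name]
                fh.write("\t".join([
                    node.name, node.parent or "",
                    " ".join(format_variant(v)
                             for v in node.defining_variants)]) + "\n")
        finally:
            if close:
                fh.close()


def expected_motif(tree: HaploTree, name: str) -> set[MtVariant]:
    """Cumulative derived variant set of a node, root-to-node.

    A back mutation cancels the matching earlier variant (same position,
    kind and alt).  A back mutation with no earlier match is kept as-is
    (a reversion relative to the reference; it can never be observed in an
    rCRS-relative variant list and will simply count as missing).
    """
    motif: dict = {}
    for node_name in tree.path_from_root(name):
        for v in tree.nodes[node_name].defining_variants:
            if v.is_back_mutation and v.site_key in motif:
                del motif[v.site_key]
            else:
                motif[v.site_key] = v
    return set(motif.values())


# --------------------------------------------------------------------------
# mtDNA classification
# --------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    best: str
    score: float
    found: set
    missing: set
    private: set
    ranked_alternatives: list  # [(name, score)] best first

PRIVATE_PENALTY = 0.01


def classify_mtdna(hap: HaplotypeRecord, tree: HaploTree,
                   excl: Optional[HypervariableExclusionSet] = None,
                   ) -> ClassificationResult:
    """Score every tree node against an observed haplotype.

    score(node) = |found| / |expected restricted to covered range|
    minus 0.01 per private (observed but unexpected) variant, floored at 0.
    Nodes with no expected variant in range inherit their parent's raw
    fraction (root convention: 1.0).  Ties break toward the deeper node,
    then lexicographically.
    """
    if not hap.covered_range:
        raise ValueError("no scorable range: covered_range is empty")
    observed = set(filter_hypervariable(hap.variants, excl))
    observed = {v for v in observed
                if position_in_range(v.position, hap.covered_range)}

    # root-down pass so unscorable nodes can inherit the parent fraction
    fraction: dict[str, float] = {}
    detail: dict[str, tuple] = {}
    inherited: dict[str, bool] = {}
    results = []
    for name in sorted(tree.nodes, key=tree.depth):
        expected = {v for v in expected_motif(tree, name)
                    if position_in_range(v.position, hap.covered_range)}
        found = expected & observed
        private = observed - expected
        inherited[name] = not expected
        if expected:
            fraction[name] = len(found) / len(expected)
        else:
            parent = tree.nodes[name].parent
            fraction[name] = fraction[parent] if parent else 1.0
        detail[name] = (found, expected - found, private)
        score = max(0.0, fraction[name] - PRIVATE_PENALTY * len(private))
        results.append((name, score))

    # ties: evidence-backed nodes beat score-inheriting ones; among the
    # former the deeper node wins, among the latter the shallower (a node
    # with no scorable variants never outranks what it inherited from)
    results.sort(key=lambda item: (
        -item[1], inherited[item[0]],
        tree.depth(item[0]) if inherited[item[0]] else -tree.depth(item[0]),
        item[0]))
    best, best_score = results[0]
    found, missing, private = detail[best]
    return ClassificationResult(best=best, score=best_score, found=found,
                                missing=missing, private=private,
                                ranked_alternatives=results)


def write_classification_report(rows, path_or_buf):
    """rows: iterable of (sample_id, ClassificationResult)."""
    close = isinstance(path_or_buf, str)
    fh = open(path_or_buf, "w") if close else path_or_buf
    try:
        fh.write("sample_id\thaplogroup\tscore\tfound\tmissing\tprivate\n")
        for sample_id, res in rows:
            fmt = lambda s: " ".join(sorted(format_variant(v) for v in s))
            fh.write(f"{sample_id}\t{res.best}\t{res.score:.4f}\t"
                     f"{fmt(res.found)}\t{fmt(res.missing)}\t"
                     f"{fmt(res.private)}\n")
    finally:
        if close:
            fh.close()


# --------------------------------------------------------------------------
# Y-chromosome SNP classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class YMarker:
    name: str          # e.g. M242, M3
    ancestral_allele: str
    derived_allele: str
    branch: str        # HaploNode name the marker tags


def _compress_names(names: Sequence[str], stem: str) -> str:
    """Render tested-negative daughter clades compactly.

    Sibling names that are the stem plus one trailing letter forming a
    contiguous run collapse to e.g. ``Q1a3a1a-c``.
    """
    names = sorted(names)
    suffixes = [n[len(stem):] for n in names]
    if (len(names) > 1 and all(n.startswith(stem) for n in names)
            and all(len(s) == 1 and s.isalpha() for s in suffixes)):
        codes = [ord(s) for s in suffixes]
        if codes == list(range(codes[0], codes[0] + len(codes))):
            return f"{stem}{suffixes[0]}-{suffixes[-1]}"
    return ", ".join(names)


def classify_y(calls: Mapping[str, str], ytree: HaploTree,
               panel: Sequence[YMarker]) -> str:
    """Assign a Y profile to the deepest derived branch.

    ``calls`` maps marker name to the observed allele; markers absent from
    ``calls`` are untested (skipped, never assumed ancestral).  The label is
    rendered ``X*(×negatives)`` when tested markers on descendant branches
    are all ancestral.
    """
    by_branch: dict[str, YMarker] = {}
    for mk in panel:
        if mk.branch in by_branch:
            raise TreeError(f"two markers map to branch {mk.branch!r}")
        by_branch[mk.branch] = mk

    def status(branch: str) -> Optional[bool]:
        mk = by_branch.get(branch)
        if mk is None or mk.name not in calls:
            return None  # untested
        allele = calls[mk.name].upper()
        if allele == mk.derived_allele.upper():
            return True
        if allele == mk.ancestral_allele.upper():
            return False
        raise ValueError(f"marker {mk.name}: allele {allele!r} matches "
                         "neither ancestral nor derived state")

    # consistency + candidate search
    derived_nodes = [n for n in ytree.nodes if status(n) is True]
    for n in derived_nodes:
        for anc in ytree.path_from_root(n)[:-1]:
            if status(anc) is False:
                raise IncompatibleCallsError(
                    f"derived at {by_branch[n].name} ({n}) but ancestral at "
                    f"{by_branch[anc].name} ({anc})")
    if not derived_nodes:
        return "unresolved"
    best = max(derived_nodes, key=lambda n: (ytree.depth(n), n))

    # tested-and-ancestral branches below the assignment
    negatives = [n for n in ytree.descendants(best) if status(n) is False]
    if negatives:
        return f"{best}*(×{_compress_names(negatives, best)})"
    return best


# --------------------------------------------------------------------------
# Bundled demo trees
# --------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("lineagekit") / "data" / name


def load_demo_tree() -> HaploTree:
    """Small bundled mtDNA haplogroup tree (A2/B2/C1/L3b and the B2t area)."""
    with (_data_path("demo_mt_tree.tsv")).open() as fh:
        return HaploTree.from_tsv(fh)


def load_demo_ytree() -> tuple[HaploTree, list[YMarker]]:
    """Bundled Y-SNP hierarchy and marker panel."""
    with (_data_path("demo_y_tree.tsv")).open() as fh:
        tree = HaploTree.from_tsv(fh)
    markers = []
    with (_data_path("demo_y_markers.tsv")).open() as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                name, anc, der, branch = line.rstrip("\n").split("\t")
                markers.append(YMarker(name, anc, der, branch))
    return tree, markers
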