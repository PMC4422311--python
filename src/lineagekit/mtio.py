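"""Reading, writing and the rCRS-relative mutation nomenclature.

Human mtDNA variation is conventionally reported as a list of positions on
the 16,569-bp revised Cambridge Reference Sequence (rCRS), using a compact
token grammar: ``T16362C`` is a substitution, a bare alt suffix marks a
transversion relative to the reference base, ``@`` prefixes a back mutation
(reversion), ``573.XC`` an insertion of a variable-length C run, ``249d`` a
deletion, and trailing tags (``s``, ``-t``, ``-r``, ``-nc``, an amino-acid
replacement in round brackets) annotate the functional class of a change.
This module parses and formats that grammar, diffs aligned sequences into
variant lists, applies the standard hypervariable-site exclusions, and reads
and writes the tabular haplotype format used throughout the package.

Coordinates are 1-based and closed; the molecule is circular and a covered
range may wrap through position 16569 (control-region tables typically cover
16024-576).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RCRS_LENGTH = 16569

# IUPAC ambiguity codes signalling point heteroplasmy in mtDNA tables.
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
NUCLEOTIDES = set("ACGT")

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class VariantParseError(ValueError):
    """A token does not match the rCRS-relative variant grammar."""


class AlignmentError(ValueError):
    """Sequences passed to diff/apply are not position-compatible."""


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


# --------------------------------------------------------------------------
# MtVariant
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MtVariant:
    """One rCRS-relative variant.

    Identity (equality/hash) is defined by ``(position, kind, alt,
    is_back_mutation)``: the reference base is contextual information, the
    annotation tag is opaque metadata, and insertion run lengths are ignored
    so that ``573.XC`` and ``573.1C`` denote the same length polymorphism.
    """

    position: int
    kind: str  # 'sub' | 'ins' | 'del'
    ref_base: Optional[str] = None
    alt: Optional[str] = None
    is_back_mutation: bool = False
    annotation: Optional[str] = None
    ins_length: Optional[int] = None  # concrete run length when known

    def __post_init__(self):
        if not (1 <= self.position <= RCRS_LENGTH):
            raise VariantParseError(
                f"position {self.position} outside [1, {RCRS_LENGTH}]")
        if self.kind not in ("sub", "ins", "del"):
            raise VariantParseError(f"unknown variant kind {self.kind!r}")
        if self.kind == "sub":
            if self.alt is None:
                raise VariantParseError("substitution requires an alt base")
            if self.ref_base is not None and self.ref_base == self.alt:
                raise VariantParseError(
                    f"substitution at {self.position} has ref == alt")

    # -- identity -----------------------------------------------------------
    @property
    def key(self):
        return (self.position, self.kind, self.alt, self.is_back_mutation)

    @property
    def site_key(self):
        """Identity with the back-mutation flag stripped (for cancellation)."""
        return (self.position, self.kind, self.alt)

    def __eq__(self, other):
        return isinstance(other, MtVariant) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    # -- derived properties -------------------------------------------------
    @property
    def is_heteroplasmy(self) -> bool:
        return self.kind == "sub" and self.alt in IUPAC_AMBIGUOUS

    @property
    def is_transition(self) -> Optional[bool]:
        """True/False for substitutions with a known reference base."""
        if self.kind != "sub" or self.ref_base is None:
            return None
        if self.alt not in NUCLEOTIDES:
            return None
        return TRANSITION_PARTNER[self.ref_base] == self.alt

    def as_back_mutation(self) -> "MtVariant":
        return replace(self, is_back_mutation=True)

    def base_variant(self) -> "MtVariant":
        return replace(self, is_back_mutation=False)

    def __str__(self) -> str:
        return format_variant(self)


_TOKEN_RE = re.compile(
    r"""^(?P<back>@{1,2})?
        (?P<ref>[ACGT])?
        (?P<pos>\d+)
        (?P<body>\.(?:X|\d+)[ACGT]|\+[ACGT]+|d|del|[ACGTRYSWKMBDHVN])?
        (?P<ann>s|-t|-r|-nc|\([^()]*\))?$""",
    re.VERBOSE,
)


def parse_variant(token: str, reference: Optional[str] = None) -> MtVariant:
    """Parse one variant token.

    ``reference``, when given, is the full reference sequence (1-based
    indexing via ``reference[pos - 1]``) used to resolve the reference base
    of tokens that omit it and the alt base of bare transition tokens such
    as ``16092``.
    """
    if not token:
        raise VariantParseError("empty variant token")
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if not (1 <= pos <= RCRS_LENGTH):
        raise VariantParseError(
            f"position {pos} in token {token!r} outside [1, {RCRS_LENGTH}]")
    back = m.group("back") is not None
    ref = m.group("ref")
    if ref is None and reference is not None:
        ref = reference[pos - 1].upper()
    body = m.group("body")
    ann = m.group("ann")

    if body is None:
        # bare position: a transition relative to the reference base
        if ref is None:
            raise VariantParseError(
                f"token {token!r} is a bare transition but no reference "
                "base is available")
        return MtVariant(pos, "sub", ref_base=ref,
                         alt=TRANSITION_PARTNER[ref],
                         is_back_mutation=back, annotation=ann)
    if body in ("d", "del"):
        return MtVariant(pos, "del", ref_base=ref, alt=None,
                         is_back_mutation=back, annotation=ann)
    if body.startswith("."):
        length_part, base = body[1:-1], body[-1]
        length = None if length_part == "X" else int(length_part)
        return MtVariant(pos, "ins", ref_base=ref, alt=base,
                         is_back_mutation=back, annotation=ann,
                         ins_length=length)
    if body.startswith("+"):
        run = body[1:]
        if len(set(run)) != 1:
            raise VariantParseError(
                f"insertion token {token!r} mixes bases in one run")
        return MtVariant(pos, "ins", ref_base=ref, alt=run[0],
                         is_back_mutation=back, annotation=ann,
                         ins_length=len(run))
    # single-letter body: an explicit alt base (substitution)
    return MtVariant(pos, "sub", ref_base=ref, alt=body,
                     is_back_mutation=back, annotation=ann)


def format_variant(v: MtVariant) -> str:
    """Render a variant in the standard token grammar."""
    prefix = "@" if v.is_back_mutation else ""
    ref = v.ref_base or ""
    ann = v.annotation or ""
    if v.kind == "sub":
        return f"{prefix}{ref}{v.position}{v.alt}{ann}"
    if v.kind == "del":
        return f"{prefix}{ref}{v.position}d{ann}"
    length = "X" if v.ins_length is None else str(v.ins_length)
    return f"{prefix}{v.position}.{length}{v.alt}{ann}"


# --------------------------------------------------------------------------
# Sequence records and diffing
# --------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """An aligned nucleotide stretch anchored on the rCRS coordinate system."""

    id: str
    sequence: str
    coordinate_offset: int = 1  # rCRS position of the first column

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - (NUCLEOTIDES | IUPAC_AMBIGUOUS | {"-"})
        if bad:
            raise ValueError(f"illegal characters in sequence: {sorted(bad)}")


def diff_sequences(query: SequenceRecord,
                   reference: SequenceRecord) -> list[MtVariant]:
    """Minimal variant list transforming ``reference`` into ``query``.

    Both records must be position-matched columns of the same alignment
    (gaps as ``-``).  Reference positions advance only on non-gap reference
    columns; insertions attach to the preceding reference position, runs of
    a single base collapsing into one variable-length insertion variant.
    """
    if len(query.sequence) != len(reference.sequence):
        raise AlignmentError(
            f"aligned lengths differ: {len(query.sequence)} vs "
            f"{len(reference.sequence)}")
    if query.coordinate_offset != reference.coordinate_offset:
        raise AlignmentError("records anchored at different offsets")

    out: list[MtVariant] = []
    pos = reference.coordinate_offset - 1  # last consumed reference position
    i = 0
    n = len(reference.sequence)
    while i < n:
        r = reference.sequence[i]
        q = query.sequence[i]
        if r == "-":
            if q != "-":
                # insertion run of identical inserted bases
                run = [q]
                j = i + 1
                while j < n and reference.sequence[j] == "-" \
                        and query.sequence[j] == q:
                    run.append(q)
                    j = j + 1
                out.append(MtVariant(pos if pos >= 1 else 1, "ins",
                                     alt=q, ins_length=len(run)))
                i = j
                continue
            i += 1
            continue
        pos += 1
        if pos > RCRS_LENGTH:
            pos -= RCRS_LENGTH  # circular wrap
        if q == "-":
            out.append(MtVariant(pos, "del", ref_base=r, alt=None))
        elif q != r:
            out.append(MtVariant(pos, "sub", ref_base=r, alt=q))
        i += 1
    return out


def apply_variants(reference: SequenceRecord,
                   variants: Iterable[MtVariant]) -> SequenceRecord:
    """Apply a variant list to a reference, inverting :func:`diff_sequences`.

    Returns an ungapped sequence; insertion variants with unknown run length
    insert a single copy of the run base.
    """
    by_pos: dict[int, list[MtVariant]] = {}
    for v in variants:
        by_pos.setdefault(v.position, []).append(v)
    out = []
    offset = reference.coordinate_offset
    seq = reference.sequence.replace("-", "")
    for i, base in enumerate(seq):
        pos = offset + i
        if pos > RCRS_LENGTH:
            pos -= RCRS_LENGTH
        here = by_pos.get(pos, [])
        subs = [v for v in here if v.kind == "sub"]
        dels = [v for v in here if v.kind == "del"]
        inss = [v for v in here if v.kind == "ins"]
        if dels:
            pass  # base removed
        elif subs:
            out.append(subs[0].alt)
        else:
            out.append(base)
        for v in inss:
            out.append(v.alt * (v.ins_length or 1))
    return SequenceRecord(reference.id, "".join(out),
                          reference.coordinate_offset)


# --------------------------------------------------------------------------
# Hypervariable exclusions
# --------------------------------------------------------------------------

def _default_excluded_subs():
    return frozenset({
        MtVariant(16182, "sub", ref_base="A", alt="C"),
        MtVariant(16183, "sub", ref_base="A", alt="C"),
        MtVariant(16519, "sub", ref_base="T", alt="C"),
    })


@dataclass(frozen=True)
class HypervariableExclusionSet:
    """Sites dropped before network building, classification and dating.

    Defaults follow common mtDNA practice: the A16182C/A16183C length-
    variation associates, the hypermutable T16519C, the length-variation
    window around position 310 (309-315), and point heteroplasmies.
    """

    excluded_substitutions: frozenset = field(
        default_factory=_default_excluded_subs)
    excluded_regions: tuple = ((309, 315),)
    exclude_heteroplasmies: bool = True

    def excludes(self, v: MtVariant) -> bool:
        if v.base_variant() in self.excluded_substitutions:
            return True
        for lo, hi in self.excluded_regions:
            if lo <= v.position <= hi:
                return True
        if self.exclude_heteroplasmies and v.is_heteroplasmy:
            return True
        return False


def filter_hypervariable(variants: Sequence[MtVariant],
                         excl: Optional[HypervariableExclusionSet] = None,
                         ) -> list[MtVariant]:
    """Drop excluded variants, preserving order."""
    if excl is None:
        excl = HypervariableExclusionSet()
    return [v for v in variants if not excl.excludes(v)]


# --------------------------------------------------------------------------
# Haplotype records and tables
# --------------------------------------------------------------------------

def _parse_range(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        lo, _, hi = part.partition("-")
        out.append((int(lo), int(hi) if hi else int(lo)))
    return out


def _format_range(intervals) -> str:
    return ";".join(f"{lo}-{hi}" for lo, hi in intervals)


def position_in_range(pos: int, intervals) -> bool:
    """Closed-interval membership; an interval with start > end wraps
    through position 16569 (circular control region, e.g. 16024-576)."""
    for lo, hi in intervals:
        if lo <= hi:
            if lo <= pos <= hi:
                return True
        elif pos >= lo or pos <= hi:
            return True
    return False


@dataclass
class HaplotypeRecord:
    sample_id: str
    population: str  # e.g. 'Ladino' or 'Maya'
    ethnic_group: str  # e.g. Q'eqchi', Poqomchi', K'iche'
    covered_range: list = field(default_factory=lambda: [(16024, 576)])
    variants: list = field(default_factory=list)
    assigned_haplogroup: Optional[str] = None

    def validate(self):
        for v in self.variants:
            if not position_in_range(v.position, self.covered_range):
                raise ValueError(
                    f"{self.sample_id}: variant {v} outside covered range")
        seen: dict = {}
        for v in self.variants:
            prev = seen.get(v.site_key)
            if prev is not None and prev.is_back_mutation == v.is_back_mutation:
                raise ValueError(
                    f"{self.sample_id}: duplicate variant {v}")
            seen[v.site_key] = v
        return self


HAPLOTABLE_COLUMNS = ["sample_id", "population", "ethnic_group", "range",
                      "variants", "haplogroup"]


def read_haplotype_table(path_or_buf,
                         reference: Optional[str] = None
                         ) -> list[HaplotypeRecord]:
    """Read the tab-separated haplotype table.

    Columns: sample_id, population, ethnic_group, range (semicolon list of
    1-based closed intervals), variants (space-separated tokens, empty for
    the reference haplotype), haplogroup (may be empty).
    """
    close = False
    if isinstance(path_or_buf, (str,)):
        fh = open(path_or_buf)
        close = True
    else:
        fh = path_or_buf
    try:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in HAPLOTABLE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        idx = {c: header.index(c) for c in HAPLOTABLE_COLUMNS}
        records = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            try:
                variants = [parse_variant(t, reference)
                            for t in cells[idx["variants"]].split() if t]
            except VariantParseError as e:
                raise VariantParseError(f"row {lineno}: {e}") from e
            records.append(HaplotypeRecord(
                sample_id=cells[idx["sample_id"]],
                population=cells[idx["population"]],
                ethnic_group=cells[idx["ethnic_group"]],
                covered_range=_parse_range(cells[idx["range"]]),
                variants=variants,
                assigned_haplogroup=cells[idx["haplogroup"]] or None,
            ).validate())
        return records
    finally:
        if close:
            fh.close()


def write_haplotype_table(records: Sequence[HaplotypeRecord], path_or_buf):
    close = False
    if isinstance(path_or_buf, str):
        fh = open(path_or_buf, "w", newline="")
        close = True
    else:
        fh = path_or_buf
    try:
        fh.write("\t".join(HAPLOTABLE_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.sample_id, r.population, r.ethnic_group,
                _format_range(r.covered_range),
                " ".join(format_variant(v) for v in r.variants),
                r.assigned_haplogroup or "",
            ]) + "\n")
    finally:
        if close:
            fh.close()


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq))
            for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Sequence[SequenceRecord], path):
    SeqIO.write([SeqRecord(Seq(r.sequence), id=r.id, description="")
                 for r in records], path, "fasta")


def synthetic_reference(seed: int = 0, length: int = RCRS_LENGTH) -> str:
    """Deterministic synthetic 16,569-bp reference stand-in.

    This is NOT the rCRS; it is a synthetic sequence with a uniform base
    composition used wherever tests need a full-length coordinate frame
    without embedding the real reference.  Real analyses should load the
    rCRS from a user-supplied FASTA.
    """
    import numpy as np
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))
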