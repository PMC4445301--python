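"""Core genotype algebra for polyploid SNP-array calls.

A probe on an allopolyploid array may hybridise to one genomic locus or to a
pair of homoeologous loci (one per sub-genome).  The observed fluorescence
call at a sample is then the *superposition* of the signals of all alleles
the probe binds: an A-channel allele anywhere yields AA, a B-channel allele
yields BB, both together yield a heterozygous-looking AB, and no binding at
all yields NC (no call).  This module holds the call vocabulary, the
two-locus allele state, the superposition rule, parental polymorphism-
combination typing, and the non-parental-genotype (NPG) predicate that the
filtering layers build on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Call(str, enum.Enum):
    """An observed array call at one locus in one sample.

    AA/AB/BB are genotype-cluster assignments, NC is a hybridised sample
    that fell outside every cluster, and MISSING ("-") is a manually
    rescored / absent datum.  MISSING is excluded from every numerator and
    denominator downstream; NC is an informative observed state.
    """

    AA = "AA"
    AB = "AB"
    BB = "BB"
    NC = "NC"
    MISSING = "-"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.value


#: The four observed (countable) states, in canonical report order.
OBSERVED_CALLS: tuple[Call, ...] = (Call.AA, Call.AB, Call.BB, Call.NC)


class Allele(str, enum.Enum):
    """State of one underlying genomic locus with respect to a probe.

    A / B bind the probe and light the respective channel.  NULL means the
    locus exists but carries enough mismatches that the probe does not bind
    (a "null allele").  ABSENT means the probe targets a single genomic
    locus and there is no homoeologous second locus at all; it is only
    meaningful in the second slot of an :class:`AlleleState`.
    """

    A = "A"
    B = "B"
    NULL = "null"
    ABSENT = "absent"


@dataclass(frozen=True)
class AlleleState:
    """Underlying two-locus allele configuration of one (haploid) genome.

    ``locus2 == Allele.ABSENT`` encodes the single-locus (Simple SNP) case.
    ``locus1`` must be a real locus (A, B or NULL).
    """

    locus1: Allele
    locus2: Allele

    def __post_init__(self) -> None:
        if self.locus1 is Allele.ABSENT:
            raise ValueError("locus1 cannot be ABSENT; a probe targets at least one locus")

    @property
    def single_locus(self) -> bool:
        return self.locus2 is Allele.ABSENT

    def swapped(self) -> "AlleleState":
        """Exchange the two underlying loci (no-op for single-locus states)."""
        if self.single_locus:
            return self
        return AlleleState(self.locus2, self.locus1)

    def __str__(self) -> str:
        return f"{self.locus1.value}/{self.locus2.value}"


def superpose(state: AlleleState) -> Call:
    """Observed call produced by the union of bound alleles of ``state``.

    {A} -> AA, {B} -> BB, {A,B} -> AB, {} -> NC.  Total and symmetric in
    the two locus slots.
    """
    bound = {a for a in (state.locus1, state.locus2) if a in (Allele.A, Allele.B)}
    if bound == {Allele.A, Allele.B}:
        return Call.AB
    if bound == {Allele.A}:
        return Call.AA
    if bound == {Allele.B}:
        return Call.BB
    return Call.NC


@dataclass(frozen=True)
class ParentPair:
    """The two parental calls at one locus (p1 = parent 1, p2 = parent 2)."""

    p1: Call
    p2: Call

    @property
    def typeable(self) -> bool:
        return Call.MISSING not in (self.p1, self.p2)

    @property
    def calls(self) -> frozenset[Call]:
        return frozenset((self.p1, self.p2))


class PolymorphismKind(enum.Enum):
    """Parental polymorphism-combination classes.

    Four monomorphic kinds (identical parental calls) and six unordered
    polymorphic kinds.  NC counts as a genuine parental state, so AA/NC is
    polymorphic.
    """

    MONO_AA = ("AA", "AA")
    MONO_AB = ("AB", "AB")
    MONO_BB = ("BB", "BB")
    MONO_NC = ("NC", "NC")
    POLY_AA_BB = ("AA", "BB")
    POLY_AA_AB = ("AA", "AB")
    POLY_AA_NC = ("AA", "NC")
    POLY_BB_AB = ("BB", "AB")
    POLY_BB_NC = ("BB", "NC")
    POLY_AB_NC = ("AB", "NC")

    @property
    def monomorphic(self) -> bool:
        return self.name.startswith("MONO")

    @property
    def canonical_calls(self) -> tuple[Call, Call]:
        a, b = self.value
        return Call(a), Call(b)


class Orientation(enum.Enum):
    """Whether (p1, p2) matches the kind's canonical call order."""

    P1_FIRST = "p1_first"
    P2_FIRST = "p2_first"


@dataclass(frozen=True)
class PolymorphismCombination:
    kind: PolymorphismKind
    orientation: Orientation

    @property
    def monomorphic(self) -> bool:
        return self.kind.monomorphic


_KIND_BY_CALLS = {frozenset(k.value): k for k in PolymorphismKind}


def type_parent_pair(p1: Call, p2: Call) -> PolymorphismCombination:
    """Map a parental call pair to its polymorphism combination.

    Monomorphic iff ``p1 == p2``; polymorphic kinds are unordered with an
    orientation flag recording which parent carries the kind's first call.
    Raises ``ValueError`` on a MISSING parent (such loci are untypeable).
    """
    if Call.MISSING in (p1, p2):
        raise ValueError("cannot type a parent pair with a MISSING call")
    kind = _KIND_BY_CALLS[frozenset((p1.value, p2.value))]
    if p1 == p2 or p1 is kind.canonical_calls[0]:
        orient = Orientation.P1_FIRST
    else:
        orient = Orientation.P2_FIRST
    return PolymorphismCombination(kind, orient)


def is_parental(call: Call, pair: ParentPair) -> bool:
    """True iff ``call`` equals either parental call (else it is an NPG).

    MISSING must never reach this predicate: missing cells are excluded
    from PNPG numerators and denominators upstream.
    """
    if call is Call.MISSING:
        raise ValueError("MISSING calls are excluded before NPG testing")
    return call is pair.p1 or call is pair.p2
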