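"""Classification of polymorphic loci: Simple / sHemi / mHemi / Pseudo-simple.

A doubled-haploid progeny inherits, at each of the (up to) two genomic loci
a probe binds, one parental allele with probability 1/2, independently when
the loci are unlinked.  Enumerating the four equiprobable allele
combinations through the signal-superposition rule yields, for every
parental two-locus configuration, an expected progeny call distribution
with frequencies in {0, 1/4, 1/2, 3/4}.  Loci whose probes superpose two
loci betray themselves either by non-parental calls in the progeny
(locus PNPG above threshold) or — for the AA/NC and BB/NC parental pairs,
whose multi-locus variant shows no NPG at all — by a 3:1 instead of 1:1
segregation ratio, discriminated by a Pearson chi-square goodness-of-fit
test.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from scipy.stats import chi2 as _chi2_dist

from .core import (
    Allele,
    AlleleState,
    Call,
    ParentPair,
    PolymorphismKind,
    superpose,
    type_parent_pair,
)


class SnpClass(enum.Enum):
    SIMPLE = "Simple"
    S_HEMI = "sHemi"
    M_HEMI = "mHemi"
    PSEUDO_SIMPLE = "Pseudo-simple"
    UNCLASSIFIED = "Unclassified"

    @property
    def single_locus(self) -> bool:
        return self in (SnpClass.SIMPLE, SnpClass.S_HEMI)


@dataclass(frozen=True)
class SegregationExpectation:
    """Expected DH progeny call distribution for one parental configuration group.

    Parental two-locus states producing the same (parental call pair,
    progeny distribution) are collapsed into one group; ``parent_states``
    retains every generating state pair (parent order and locus order
    canonicalised).  ``npg_calls`` are the progeny calls absent from both
    parents.  ``degenerate`` marks two-locus groups whose progeny behave
    exactly like a single-locus Simple SNP (indistinguishable from array
    data alone).
    """

    group_id: int
    snp_class: SnpClass
    parent_calls: ParentPair
    expected_freqs: Mapping[Call, Fraction]
    npg_calls: frozenset[Call]
    parent_states: tuple[tuple[AlleleState, AlleleState], ...]
    degenerate: bool = False

    @property
    def npg_frequency(self) -> Fraction:
        return sum((self.expected_freqs[c] for c in self.npg_calls), Fraction(0))


def dh_progeny_distribution(p1: AlleleState, p2: AlleleState) -> dict[Call, Fraction]:
    """Brute-force the four equiprobable DH allele combinations through superposition."""
    dist: dict[Call, Fraction] = {}
    for l1, l2 in itertools.product((p1.locus1, p2.locus1), (p1.locus2, p2.locus2)):
        call = superpose(AlleleState(l1, l2))
        dist[call] = dist.get(call, Fraction(0)) + Fraction(1, 4)
    return dist


_REAL = (Allele.A, Allele.B, Allele.NULL)


def _single_states() -> list[AlleleState]:
    return [AlleleState(a, Allele.ABSENT) for a in _REAL]


def _two_states() -> list[AlleleState]:
    return [AlleleState(a, b) for a in _REAL for b in _REAL]


def _simple_distribution(pair: ParentPair) -> dict[Call, Fraction] | None:
    """Distribution a single-locus probe with these parental calls would give."""
    mapping = {
        Call.AA: Allele.A,
        Call.BB: Allele.B,
        Call.NC: Allele.NULL,
    }
    if pair.p1 not in mapping or pair.p2 not in mapping:
        return None
    return dh_progeny_distribution(
        AlleleState(mapping[pair.p1], Allele.ABSENT),
        AlleleState(mapping[pair.p2], Allele.ABSENT),
    )


def _canonical_pair(p1: AlleleState, p2: AlleleState):
    key = lambda s: (s.locus1.value, s.locus2.value)
    variants = [tuple(sorted((p1, p2), key=key)), tuple(sorted((p1.swapped(), p2.swapped()), key=key))]
    return min(variants, key=lambda v: (key(v[0]), key(v[1])))


def enumerate_expectations(include_single: bool = True) -> list[SegregationExpectation]:
    """All distinguishable polymorphic segregation groups of the superposition model.

    Covers every parental AlleleState pair (single-locus and two-locus)
    whose observed parental calls differ, collapsing pairs that yield the
    same parental calls and progeny distribution.  Group ids are assigned
    deterministically: Pseudo-simple groups first, then sHemi, mHemi,
    degenerate two-locus Simple-like groups, and finally — when
    ``include_single`` — the true single-locus Simple groups.
    """
    buckets: dict[tuple, dict] = {}

    def visit(p1: AlleleState, p2: AlleleState) -> None:
        c1, c2 = superpose(p1), superpose(p2)
        if c1 == c2:
            return  # monomorphic: no classification, line-filter territory
        pair = ParentPair(c1, c2)
        dist = dh_progeny_distribution(p1, p2)
        dist_key = tuple(sorted((c.value, f) for c, f in dist.items()))
        key = (tuple(sorted((c1.value, c2.value))), dist_key)
        b = buckets.setdefault(key, {"pair": pair, "dist": dist, "states": set()})
        b["states"].add(_canonical_pair(p1, p2))

    for p1, p2 in itertools.product(_two_states(), repeat=2):
        visit(p1, p2)
    single_keys = set()
    if include_single:
        for p1, p2 in itertools.product(_single_states(), repeat=2):
            c1, c2 = superpose(p1), superpose(p2)
            if c1 == c2:
                continue
            before = set(buckets)
            visit(p1, p2)
            dist = dh_progeny_distribution(p1, p2)
            dist_key = tuple(sorted((c.value, f) for c, f in dist.items()))
            single_keys.add((tuple(sorted((c1.value, c2.value))), dist_key))

    groups = []
    for key, b in buckets.items():
        pair: ParentPair = b["pair"]
        dist = b["dist"]
        npg = frozenset(c for c in dist if c not in pair.calls)
        simple_like = _simple_distribution(pair)
        is_single = key in single_keys
        two_locus_states = tuple(
            sp for sp in b["states"] if not (sp[0].single_locus and sp[1].single_locus)
        )
        if Call.AB in pair.calls:
            cls = SnpClass.M_HEMI if npg else SnpClass.S_HEMI
            degenerate = False
        elif npg or dist != simple_like:
            cls = SnpClass.PSEUDO_SIMPLE
            degenerate = False
        else:
            cls = SnpClass.SIMPLE
            degenerate = not is_single and bool(two_locus_states)
        groups.append((cls, pair, dist, npg, tuple(sorted(b["states"], key=str)), degenerate))

    order = {
        SnpClass.PSEUDO_SIMPLE: 0,
        SnpClass.S_HEMI: 1,
        SnpClass.M_HEMI: 2,
        SnpClass.SIMPLE: 3,
    }
    groups.sort(key=lambda g: (order[g[0]], g[5], sorted(c.value for c in g[1].calls), str(g[2])))
    out = []
    for gid, (cls, pair, dist, npg, states, degenerate) in enumerate(groups, start=1):
        out.append(
            SegregationExpectation(
                group_id=gid,
                snp_class=cls,
                parent_calls=pair,
                expected_freqs=dict(dist),
                npg_calls=npg,
                parent_states=states,
                degenerate=degenerate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pearson goodness of fit


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: Mapping[Call, float]
    observed_counts: Mapping[Call, int]


def chisq_goodness_of_fit(
    observed: Mapping[Call, int],
    expected_freqs: Mapping[Call, float],
    min_count: int = 30,
    continuity: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square of observed call counts against expected fractions.

    Only cells with positive expected fraction enter the statistic;
    df = (number of such cells) − 1.  ``continuity`` applies the Yates
    correction (off by default).  Raises ``ValueError`` when the total
    count over supported cells is below ``min_count`` (the caller marks
    such loci Unclassified).
    """
    cells = [c for c, f in expected_freqs.items() if f > 0]
    total_f = float(sum(expected_freqs[c] for c in cells))
    if abs(total_f - 1.0) > 1e-9:
        raise ValueError("expected frequencies must sum to 1")
    n = int(sum(int(observed.get(c, 0)) for c in cells))
    if n < min_count:
        raise ValueError(f"total observed count {n} below minimum {min_count}")
    stat = 0.0
    exp_counts: dict[Call, float] = {}
    obs_counts: dict[Call, int] = {}
    for c in cells:
        e = float(expected_freqs[c]) * n
        o = int(observed.get(c, 0))
        exp_counts[c] = e
        obs_counts[c] = o
        d = abs(o - e)
        if continuity:
            d = max(d - 0.5, 0.0)
        stat += d * d / e
    df = len(cells) - 1
    p = float(_chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return ChiSquareResult(float(stat), df, p, exp_counts, obs_counts)


# ---------------------------------------------------------------------------
# Per-locus decision procedure


@dataclass(frozen=True)
class ClassifyConfig:
    locus_threshold: float = 0.05
    alpha: float = 0.05
    min_count: int = 30
    continuity: bool = False


@dataclass(frozen=True)
class LocusClassification:
    locus_id: str
    parent_pair: ParentPair
    pnpg: float
    snp_class: SnpClass
    chi2_11: ChiSquareResult | None = None
    chi2_31: ChiSquareResult | None = None

    @property
    def retained(self) -> bool:
        return self.snp_class.single_locus


def classify_locus(
    locus_id: str,
    parent_pair: ParentPair,
    observed: Mapping[Call, int],
    pnpg: float,
    config: ClassifyConfig = ClassifyConfig(),
) -> LocusClassification:
    """Classify one polymorphic locus from its parental calls, progeny call
    counts (authentic lines, detected calls only) and locus PNPG.

    Decision order: (a) PNPG at/above threshold means multi-locus — mHemi
    when a parent is heterozygous, Pseudo-simple otherwise; (b) below the
    threshold, AA/NC and BB/NC parental pairs are tested 1:1 versus 3:1
    (the no-NPG Pseudo-simple signature); (c) otherwise a heterozygous
    parent means sHemi, else Simple.
    """
    combo = type_parent_pair(parent_pair.p1, parent_pair.p2)
    if combo.monomorphic:
        raise ValueError(f"locus {locus_id!r} is monomorphic; classification is for polymorphic loci")
    has_ab = Call.AB in parent_pair.calls

    if pnpg >= config.locus_threshold:
        cls = SnpClass.M_HEMI if has_ab else SnpClass.PSEUDO_SIMPLE
        return LocusClassification(locus_id, parent_pair, pnpg, cls)

    if combo.kind in (PolymorphismKind.POLY_AA_NC, PolymorphismKind.POLY_BB_NC):
        hom = parent_pair.p1 if parent_pair.p1 is not Call.NC else parent_pair.p2
        counts = {hom: int(observed.get(hom, 0)), Call.NC: int(observed.get(Call.NC, 0))}
        try:
            r11 = chisq_goodness_of_fit(
                counts, {hom: Fraction(1, 2), Call.NC: Fraction(1, 2)},
                config.min_count, config.continuity,
            )
            r31 = chisq_goodness_of_fit(
                counts, {hom: Fraction(3, 4), Call.NC: Fraction(1, 4)},
                config.min_count, config.continuity,
            )
        except ValueError:
            return LocusClassification(locus_id, parent_pair, pnpg, SnpClass.UNCLASSIFIED)
        if r11.p_value >= config.alpha:
            cls = SnpClass.SIMPLE
        elif r31.p_value >= config.alpha:
            cls = SnpClass.PSEUDO_SIMPLE
        else:
            cls = SnpClass.UNCLASSIFIED
        return LocusClassification(locus_id, parent_pair, pnpg, cls, r11, r31)

    cls = SnpClass.S_HEMI if has_ab else SnpClass.SIMPLE
    return LocusClassification(locus_id, parent_pair, pnpg, cls)


def filter_loci(
    classifications: list[LocusClassification],
    remove_unclassified: bool = True,
) -> tuple[list[LocusClassification], list[LocusClassification]]:
    """Partition into (retained single-locus, removed multi-locus) sets."""
    retained, removed = [], []
    for c in classifications:
        if c.snp_class.single_locus:
            retained.append(c)
        elif c.snp_class is SnpClass.UNCLASSIFIED and not remove_unclassified:
            retained.append(c)
        else:
            removed.append(c)
    return retained, removed


def pooled_nc_test(classifications: list[LocusClassification]) -> dict:
    """Aggregate 1:1 and 3:1 tests over all AA/NC & BB/NC loci, pooled by class.

    Secondary report: counts of the homozygous parental call and NC are
    summed over loci assigned Simple and (separately) Pseudo-simple, and a
    single chi-square is computed for each pool against its expected ratio.
    """
    out: dict[str, dict] = {}
    pools = {
        SnpClass.SIMPLE: {Call.AA: Fraction(1, 2), Call.NC: Fraction(1, 2)},
        SnpClass.PSEUDO_SIMPLE: {Call.AA: Fraction(3, 4), Call.NC: Fraction(1, 4)},
    }
    for cls, freqs in pools.items():
        hom_total = nc_total = 0
        n_loci = 0
        for c in classifications:
            if c.chi2_11 is None or c.snp_class is not cls:
                continue
            hom = c.parent_pair.p1 if c.parent_pair.p1 is not Call.NC else c.parent_pair.p2
            hom_total += c.chi2_11.observed_counts[hom]
            nc_total += c.chi2_11.observed_counts[Call.NC]
            n_loci += 1
        entry: dict = {"n_loci": n_loci, "n_hom": hom_total, "n_nc": nc_total}
        if hom_total + nc_total >= 1:
            r = chisq_goodness_of_fit(
                {Call.AA: hom_total, Call.NC: nc_total}, freqs, min_count=1
            )
            entry.update(statistic=r.statistic, df=r.df, p_value=r.p_value)
        out[cls.value] = entry
    return out


def classification_frame(classifications: list[LocusClassification]):
    import pandas as pd

    rows = []
    for c in classifications:
        rows.append(
            {
                "locus_id": c.locus_id,
                "parent1_call": c.parent_pair.p1.value,
                "parent2_call": c.parent_pair.p2.value,
                "pnpg": c.pnpg,
                "chi2_11": c.chi2_11.statistic if c.chi2_11 else float("nan"),
                "p_11": c.chi2_11.p_value if c.chi2_11 else float("nan"),
                "chi2_31": c.chi2_31.statistic if c.chi2_31 else float("nan"),
                "p_31": c.chi2_31.p_value if c.chi2_31 else float("nan"),
                "class": c.snp_class.value,
                "retained": c.retained,
            }
        )
    return pd.DataFrame(rows)
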