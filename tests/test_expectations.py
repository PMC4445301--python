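"""Segregation-expectation enumeration against an independent brute-force oracle.

The oracle below re-derives observed calls and DH progeny distributions
from first principles (set union of bound alleles over the four
equiprobable allele combinations) without touching the package's
superposition code path.
"""

import itertools
from fractions import Fraction

from bifilter import Allele, AlleleState, Call, SnpClass, enumerate_expectations

# ---------------------------------------------------------------------------
# independent oracle (string-level, no package imports on the hot path)

_REAL = ("A", "B", "null")


def oracle_call(a1: str, a2: str) -> str:
    bound = {a for a in (a1, a2) if a in ("A", "B")}
    if bound == {"A", "B"}:
        return "AB"
    if bound == {"A"}:
        return "AA"
    if bound == {"B"}:
        return "BB"
    return "NC"


def oracle_dist(p1: tuple[str, str], p2: tuple[str, str]) -> dict[str, Fraction]:
    dist: dict[str, Fraction] = {}
    for l1, l2 in itertools.product((p1[0], p2[0]), (p1[1], p2[1])):
        c = oracle_call(l1, l2)
        dist[c] = dist.get(c, Fraction(0)) + Fraction(1, 4)
    return dist


def all_parent_state_pairs():
    two = [(a, b) for a in _REAL for b in _REAL]
    single = [(a, "absent") for a in _REAL]
    return itertools.chain(
        itertools.product(two, repeat=2), itertools.product(single, repeat=2)
    )


def _as_state(t: tuple[str, str]) -> AlleleState:
    m = {"A": Allele.A, "B": Allele.B, "null": Allele.NULL, "absent": Allele.ABSENT}
    return AlleleState(m[t[0]], m[t[1]])


# ---------------------------------------------------------------------------


def test_distributions_sum_to_one_with_quarter_frequencies():
    for g in enumerate_expectations():
        assert sum(g.expected_freqs.values()) == 1
        assert all(f in (Fraction(1, 4), Fraction(1, 2), Fraction(3, 4)) for f in g.expected_freqs.values())


def test_every_group_matches_bruteforce_enumeration():
    """Each stored expectation equals the oracle's distribution for each of
    its generating parental state pairs, and the oracle finds no
    polymorphic configuration outside the enumerated groups (exhaustive)."""
    groups = enumerate_expectations()
    by_key = {}
    for g in groups:
        key = (
            frozenset(c.value for c in g.parent_calls.calls),
            tuple(sorted((c.value, f) for c, f in g.expected_freqs.items())),
        )
        assert key not in by_key, "groups must be distinct"
        by_key[key] = g

    seen = set()
    for p1, p2 in all_parent_state_pairs():
        c1, c2 = oracle_call(*p1), oracle_call(*p2)
        if c1 == c2:
            continue
        dist = oracle_dist(p1, p2)
        key = (frozenset((c1, c2)), tuple(sorted(dist.items())))
        assert key in by_key, f"missing group for parents {p1}/{p2}"
        g = by_key[key]
        expected_npg = {c for c in dist if c not in (c1, c2)}
        assert {c.value for c in g.npg_calls} == expected_npg
        seen.add(key)
    assert seen == set(by_key), "enumerated groups not generated by any parent pair"


def test_group_membership_covers_generating_states():
    """The canonicalised generating states stored on each group reproduce
    the group's distribution through the oracle."""
    for g in enumerate_expectations():
        assert g.parent_states
        for s1, s2 in g.parent_states:
            d = oracle_dist(
                (s1.locus1.value.replace("absent", "absent"), s1.locus2.value),
                (s2.locus1.value, s2.locus2.value),
            )
            assert {k: v for k, v in d.items()} == {
                c.value: f for c, f in g.expected_freqs.items()
            }


def test_simple_hom_vs_nocall_segregates_one_to_one():
    groups = [
        g
        for g in enumerate_expectations()
        if g.snp_class is SnpClass.SIMPLE and g.parent_calls.calls == frozenset({Call.AA, Call.NC})
    ]
    assert len(groups) == 1
    assert groups[0].expected_freqs == {Call.AA: Fraction(1, 2), Call.NC: Fraction(1, 2)}
    assert not groups[0].npg_calls


def test_pseudo_simple_hom_vs_nocall_segregates_three_to_one():
    for hom in (Call.AA, Call.BB):
        groups = [
            g
            for g in enumerate_expectations()
            if g.snp_class is SnpClass.PSEUDO_SIMPLE
            and g.parent_calls.calls == frozenset({hom, Call.NC})
        ]
        assert len(groups) == 1
        assert groups[0].expected_freqs == {hom: Fraction(3, 4), Call.NC: Fraction(1, 4)}
        assert not groups[0].npg_calls  # indistinguishable by NPG, only by ratio


def test_shemi_groups_show_no_npg_and_mhemi_groups_do():
    groups = enumerate_expectations()
    shemi = [g for g in groups if g.snp_class is SnpClass.S_HEMI]
    mhemi = [g for g in groups if g.snp_class is SnpClass.M_HEMI]
    assert shemi and mhemi
    assert all(Call.AB in g.parent_calls.calls for g in shemi + mhemi)
    assert all(not g.npg_calls for g in shemi)
    assert all(g.npg_calls and g.npg_frequency >= Fraction(1, 4) for g in mhemi)


def test_pseudo_simple_homozygous_pairs_have_npg_segregation():
    """All AA/BB Pseudo-simple groups segregate calls absent from both parents."""
    groups = [
        g
        for g in enumerate_expectations()
        if g.snp_class is SnpClass.PSEUDO_SIMPLE
        and g.parent_calls.calls == frozenset({Call.AA, Call.BB})
    ]
    assert len(groups) == 4
    assert all(Call.AB in g.npg_calls for g in groups)
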