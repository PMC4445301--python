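"""PNPG in both matrix directions, line/locus filtering, error report."""

import numpy as np
import pandas as pd
import pytest

from bifilter import (
    Call,
    GenotypeMatrix,
    LineRecord,
    SimConfig,
    error_report,
    filter_lines,
    line_report,
    locus_report,
    pnpg_line,
    pnpg_locus,
    simulate_population,
)


def brute_force_pnpg(matrix, ids, axis):
    """Independent O(cells) loop: fraction of detected calls matching neither parent."""
    out = {}
    for ident in ids:
        det = par = 0
        if axis == "line":
            cells = [(l, ident) for l in matrix.monomorphic_loci]
        else:
            cells = [(ident, s) for s in matrix.progeny]
        for locus, sample in cells:
            call = matrix.calls.at[locus, sample]
            if call == "-":
                continue
            det += 1
            p1 = matrix.calls.at[locus, matrix.parent1]
            p2 = matrix.calls.at[locus, matrix.parent2]
            if call in (p1, p2):
                par += 1
        out[ident] = (det - par) / det
    return out


def test_line_pnpg_on_hand_matrix(tiny_matrix):
    # locA is the only monomorphic locus; DH3 has the NPG, DH4 is missing there
    rec = pnpg_line(tiny_matrix, "DH3")
    assert (rec.n_detected, rec.n_parental, rec.pnpg) == (1, 0, 1.0)
    assert not rec.authentic
    rec = pnpg_line(tiny_matrix, "DH1")
    assert rec.pnpg == 0.0 and rec.authentic


def test_line_pnpg_requires_detected_calls(tiny_matrix):
    with pytest.raises(ValueError, match="zero detected"):
        pnpg_line(tiny_matrix, "DH4")  # only MISSING at the monomorphic locus


def test_locus_pnpg_counts_npg_and_excludes_missing(tiny_matrix):
    rec = pnpg_locus(tiny_matrix, "locB")
    # DH1 AA, DH2 AB (NPG), DH3 BB, DH4 BB -> 1/4
    assert (rec.n_detected, rec.n_parental) == (4, 3)
    assert rec.pnpg == pytest.approx(0.25)
    assert not rec.reliable
    rec = pnpg_locus(tiny_matrix, "locC")
    assert rec.pnpg == 0.0 and rec.reliable


def test_filter_lines_threshold_boundary():
    mk = lambda sid, p: LineRecord(sid, 100, int(round(100 * (1 - p))), p, p < 0.05)
    kept, removed = filter_lines([mk("a", 0.049), mk("b", 0.05), mk("c", 0.2)])
    assert [r.sample_id for r in kept] == ["a"]
    assert [r.sample_id for r in removed] == ["b", "c"]


def test_both_directions_match_bruteforce_oracle():
    matrix, _ = simulate_population(
        SimConfig(
            seed=3,
            n_lines=15,
            n_monomorphic=25,
            n_simple=4,
            n_shemi=4,
            n_mhemi=4,
            n_pseudo=4,
            contamination=((0, 0.5),),
            call_error_rate=0.01,
            missing_rate=0.1,
        )
    )
    lines = {r.sample_id: r.pnpg for r in line_report(matrix)}
    assert lines == pytest.approx(brute_force_pnpg(matrix, matrix.progeny, "line"))
    poly = matrix.polymorphic_loci
    loci = {r.locus_id: r.pnpg for r in locus_report(matrix, poly)}
    expected = {}
    for lid in poly:
        det = par = 0
        p1 = matrix.calls.at[lid, "P1"]
        p2 = matrix.calls.at[lid, "P2"]
        for s in matrix.progeny:
            c = matrix.calls.at[lid, s]
            if c == "-":
                continue
            det += 1
            par += c in (p1, p2)
        expected[lid] = (det - par) / det
    assert loci == pytest.approx(expected)


def test_removing_npg_lines_never_raises_locus_pnpg(default_sim):
    """Dropping contaminated lines can only lower (or preserve) locus PNPG
    in expectation-free terms when those lines carried NPGs at the locus."""
    matrix, truth = default_sim
    poly = matrix.polymorphic_loci[:50]
    authentic = list(truth.lines.loc[truth.lines.authentic, "sample_id"])
    before = {r.locus_id: r for r in locus_report(matrix, poly)}
    after = {r.locus_id: r for r in locus_report(matrix, poly, authentic)}
    for lid in poly:
        n_npg_before = before[lid].n_detected - before[lid].n_parental
        n_npg_after = after[lid].n_detected - after[lid].n_parental
        assert n_npg_after <= n_npg_before


def test_error_report_fractions_and_weighted_mean(default_sim):
    matrix, truth = default_sim
    authentic = list(truth.lines.loc[truth.lines.authentic, "sample_id"])
    rep = error_report(matrix, samples=authentic)
    frac_cols = [c for c in rep.table.columns if c.startswith("frac_")]
    sums = rep.table[frac_cols].sum(axis=1)
    np.testing.assert_allclose(sums[rep.table.n_probes > 0], 1.0, atol=1e-12)
    # overall equals the detected-call-weighted mean of class PNPGs
    det_per_class = []
    for _, row in rep.table.iterrows():
        cls = row.parental_class
        loci = [l for l in matrix.monomorphic_loci if matrix.calls.at[l, "P1"] == cls]
        block = matrix.calls.loc[loci, authentic].to_numpy(dtype=object)
        det_per_class.append(int((block != "-").sum()))
    weighted = sum(
        d * p for d, p in zip(det_per_class, rep.table.pnpg) if d
    ) / sum(det_per_class)
    assert rep.overall_pnpg == pytest.approx(weighted, abs=1e-12)


def test_error_free_population_has_zero_pnpg(clean_sim):
    matrix, _ = clean_sim
    recs = line_report(matrix)
    assert all(r.pnpg == 0.0 for r in recs)
    rep = error_report(matrix)
    assert rep.overall_pnpg == 0.0
    for _, row in rep.table.iterrows():
        if row.n_probes:
            assert row[f"frac_{row.parental_class}"] == 1.0


def test_mean_line_pnpg_tracks_injected_error_rate(default_sim):
    """Symmetric call error at monomorphic loci always produces an NPG, so
    authentic-line PNPG should average close to the injected 1.6e-3."""
    matrix, truth = default_sim
    authentic = set(truth.lines.loc[truth.lines.authentic, "sample_id"])
    recs = [r for r in line_report(matrix) if r.sample_id in authentic]
    mean = sum(r.pnpg for r in recs) / len(recs)
    n_det = sum(r.n_detected for r in recs)
    se = (0.0016 * (1 - 0.0016) / n_det) ** 0.5
    assert mean == pytest.approx(0.0016, abs=3 * se)
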