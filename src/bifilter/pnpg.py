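"""Bi-directional PNPG (percentage of non-parental genotypes) filtering.

The same statistic is computed in both directions of the loci × samples
matrix.  Down a column (one DH line, monomorphic loci only):

    PNPG_line_j = (M_j - PG_j) / M_j

where M_j counts the line's detected (non-missing) calls and PG_j those
matching the shared parental call; a true offspring of the cross has
PNPG ~ 0, so lines at or above a threshold (default 0.05) are flagged
unauthentic.  Along a row (one polymorphic locus, authentic lines only)
the transposed formula flags loci whose probes superpose multiple genomic
loci.  The error report tabulates, per monomorphic parental class
(AA/AB/BB/NC), the fraction of every observed progeny call — the residual
NPG rate after line removal estimates the platform's call-error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Call, OBSERVED_CALLS
from .matrix import GenotypeMatrix

DEFAULT_LINE_THRESHOLD = 0.05
DEFAULT_LOCUS_THRESHOLD = 0.05

_MISS = Call.MISSING.value


@dataclass(frozen=True)
class LineRecord:
    sample_id: str
    n_detected: int
    n_parental: int
    pnpg: float
    authentic: bool


@dataclass(frozen=True)
class LocusPnpgRecord:
    locus_id: str
    n_detected: int
    n_parental: int
    pnpg: float
    reliable: bool


def _parental_mask(block: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return (block == p1[:, None]) | (block == p2[:, None])


def _counts(matrix: GenotypeMatrix, loci: list[str], samples: list[str]):
    """Detected and parental-match boolean arrays for a loci × samples block."""
    block = matrix.calls.loc[loci, samples].to_numpy(dtype=object)
    p1 = matrix.calls.loc[loci, matrix.parent1].to_numpy(dtype=object)
    p2 = matrix.calls.loc[loci, matrix.parent2].to_numpy(dtype=object)
    detected = block != _MISS
    parental = _parental_mask(block, p1, p2) & detected
    return detected, parental


def line_report(
    matrix: GenotypeMatrix,
    loci: list[str] | None = None,
    threshold: float = DEFAULT_LINE_THRESHOLD,
) -> list[LineRecord]:
    """Per-line PNPG over the given (monomorphic) loci, for every progeny sample."""
    if loci is None:
        loci = matrix.monomorphic_loci
    samples = matrix.progeny
    detected, parental = _counts(matrix, loci, samples)
    n_det = detected.sum(axis=0)
    n_par = parental.sum(axis=0)
    records = []
    for j, sid in enumerate(samples):
        if n_det[j] == 0:
            raise ValueError(f"sample {sid!r} has zero detected calls among the given loci")
        p = (n_det[j] - n_par[j]) / n_det[j]
        records.append(LineRecord(sid, int(n_det[j]), int(n_par[j]), float(p), bool(p < threshold)))
    return records


def pnpg_line(
    matrix: GenotypeMatrix,
    sample_id: str,
    loci: list[str] | None = None,
    threshold: float = DEFAULT_LINE_THRESHOLD,
) -> LineRecord:
    """PNPG of one DH line over monomorphic loci (detected calls only)."""
    if loci is None:
        loci = matrix.monomorphic_loci
    detected, parental = _counts(matrix, loci, [sample_id])
    n_det = int(detected.sum())
    if n_det == 0:
        raise ValueError(f"sample {sample_id!r} has zero detected calls among the given loci")
    n_par = int(parental.sum())
    p = (n_det - n_par) / n_det
    return LineRecord(sample_id, n_det, n_par, float(p), bool(p < threshold))


def filter_lines(
    records: list[LineRecord], threshold: float = DEFAULT_LINE_THRESHOLD
) -> tuple[list[LineRecord], list[LineRecord]]:
    """Partition lines into (kept, removed); removal at pnpg >= threshold."""
    kept = [r for r in records if r.pnpg < threshold]
    removed = [r for r in records if r.pnpg >= threshold]
    return kept, removed


def locus_report(
    matrix: GenotypeMatrix,
    loci: list[str] | None = None,
    samples: list[str] | None = None,
    threshold: float = DEFAULT_LOCUS_THRESHOLD,
) -> list[LocusPnpgRecord]:
    """Per-locus PNPG over the given (authentic) samples."""
    if loci is None:
        loci = matrix.polymorphic_loci
    if samples is None:
        samples = matrix.progeny
    detected, parental = _counts(matrix, loci, samples)
    n_det = detected.sum(axis=1)
    n_par = parental.sum(axis=1)
    records = []
    for i, lid in enumerate(loci):
        if n_det[i] == 0:
            raise ValueError(f"locus {lid!r} has zero detected calls among the given samples")
        p = (n_det[i] - n_par[i]) / n_det[i]
        records.append(
            LocusPnpgRecord(lid, int(n_det[i]), int(n_par[i]), float(p), bool(p < threshold))
        )
    return records


def pnpg_locus(
    matrix: GenotypeMatrix,
    locus_id: str,
    samples: list[str] | None = None,
    threshold: float = DEFAULT_LOCUS_THRESHOLD,
) -> LocusPnpgRecord:
    return locus_report(matrix, [locus_id], samples, threshold)[0]


@dataclass(frozen=True)
class ErrorReport:
    """Detection-error assessment over monomorphic loci, one row per parental class.

    ``table`` columns: parental_class, n_probes, frac_AA, frac_AB, frac_BB,
    frac_NC, pnpg.  Fractions are of detected progeny calls; the bolded
    diagonal of the published layout corresponds to the parental class's own
    fraction, and ``pnpg`` is one minus it.
    """

    table: pd.DataFrame
    overall_pnpg: float
    n_detected_total: int


def error_report(
    matrix: GenotypeMatrix,
    loci: list[str] | None = None,
    samples: list[str] | None = None,
) -> ErrorReport:
    """Per-parental-class call-fraction table over monomorphic loci.

    Callers should pass monomorphic loci already cleared of unreliable
    (high-PNPG) probes and the authentic samples only; the residual NPG
    rates then measure system error rather than contamination.
    """
    if loci is None:
        loci = matrix.monomorphic_loci
    if samples is None:
        samples = matrix.progeny
    block = matrix.calls.loc[loci, samples].to_numpy(dtype=object)
    pcall = matrix.calls.loc[loci, matrix.parent1].to_numpy(dtype=object)

    rows = []
    total_det = 0
    total_npg = 0
    for cls in OBSERVED_CALLS:
        sel = pcall == cls.value
        sub = block[sel]
        det = sub != _MISS
        n_det = int(det.sum())
        fracs = {}
        for c in OBSERVED_CALLS:
            fracs[f"frac_{c.value}"] = (int((sub == c.value).sum()) / n_det) if n_det else np.nan
        cls_pnpg = 1.0 - fracs[f"frac_{cls.value}"] if n_det else np.nan
        rows.append(
            {"parental_class": cls.value, "n_probes": int(sel.sum()), **fracs, "pnpg": cls_pnpg}
        )
        if n_det:
            total_det += n_det
            total_npg += n_det - int((sub == cls.value).sum())
    overall = total_npg / total_det if total_det else np.nan
    return ErrorReport(pd.DataFrame(rows), float(overall), total_det)


def line_frame(records: list[LineRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_detected": r.n_detected,
                "n_parental": r.n_parental,
                "pnpg": r.pnpg,
                "verdict": "authentic" if r.authentic else "unauthentic",
            }
            for r in records
        ]
    )


def locus_frame(records: list[LocusPnpgRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "n_detected": r.n_detected,
                "n_parental": r.n_parental,
                "pnpg": r.pnpg,
                "verdict": "reliable" if r.reliable else "unreliable",
            }
            for r in records
        ]
    )
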