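"""Reading/writing call matrices, QC pre-filters, and coded map-ready export.

The matrix file is plain delimited text (tab or comma, autodetected):
a header row of sample identifiers, a first column of locus identifiers,
and cells from ``{AA, AB, BB, NC, -}``.  Token dialects are configurable
(e.g. ``--`` as a missing marker).  The coded export recodes retained
polymorphic loci over authentic lines as ``A`` (parent-1 call), ``B``
(parent-2 call) and ``-`` (non-parental or missing), the input format of
linkage-mapping software; an R/qtl-style rotated CSV is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Call
from .matrix import GenotypeMatrix

_CANONICAL = {c.value for c in Call}


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="ascii") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path,
    parent1: str,
    parent2: str,
    delimiter: str | None = None,
    missing_tokens: tuple[str, ...] = ("-", "--", ""),
    token_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Parse a delimited call matrix; unknown tokens are reported with coordinates.

    ``token_map`` remaps dialect spellings (e.g. ``{"NoCall": "NC"}``)
    before validation; ``missing_tokens`` all map to MISSING.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "locus_id"

    remap = {t: Call.MISSING.value for t in missing_tokens}
    if token_map:
        remap.update(token_map)
    arr = df.to_numpy(dtype=object)
    for token, target in remap.items():
        arr[arr == token] = target
    bad = ~np.isin(arr, list(_CANONICAL))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown call token {arr[i, j]!r} at locus {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    clean = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return GenotypeMatrix(clean, parent1, parent2)


def write_matrix(matrix: GenotypeMatrix, path, delimiter: str = "\t") -> None:
    """ASCII, newline-terminated, no quoting; row order preserved."""
    matrix.calls.to_csv(path, sep=delimiter, lineterminator="\n")


@dataclass(frozen=True)
class PrefilterReport:
    n_loci_in: int
    n_loci_dropped: int
    dropped_loci: tuple[str, ...]
    n_samples_in: int
    n_samples_dropped: int
    dropped_samples: tuple[str, ...]


def prefilter(
    matrix: GenotypeMatrix,
    locus_detect_frac: float = 0.80,
    sample_call_rate: float = 0.70,
    count_nc_as_detected: bool = True,
) -> tuple[GenotypeMatrix, PrefilterReport]:
    """Array-level QC: drop under-detected probes, then low-call-rate samples.

    A probe is kept when detected in at least ``locus_detect_frac`` of
    samples; NC counts as detected by default because it is an informative
    state here (strict mode counts AA/AB/BB only).  Samples below
    ``sample_call_rate`` are then dropped (parents are never dropped).
    """
    arr = matrix.calls.to_numpy(dtype=object)
    detected = arr != Call.MISSING.value
    if not count_nc_as_detected:
        detected &= arr != Call.NC.value

    locus_frac = detected.mean(axis=1)
    keep_loci = locus_frac >= locus_detect_frac
    dropped_loci = tuple(matrix.calls.index[~keep_loci])

    detected = detected[keep_loci]
    sample_frac = (
        detected.mean(axis=0) if detected.shape[0] else np.ones(matrix.n_samples)
    )
    parents = {matrix.parent1, matrix.parent2}
    keep_samples = [
        s
        for k, s in enumerate(matrix.calls.columns)
        if sample_frac[k] >= sample_call_rate or s in parents
    ]
    dropped_samples = tuple(s for s in matrix.calls.columns if s not in set(keep_samples))

    out = GenotypeMatrix(
        matrix.calls.loc[keep_loci, keep_samples].copy(), matrix.parent1, matrix.parent2
    )
    report = PrefilterReport(
        n_loci_in=matrix.n_loci,
        n_loci_dropped=len(dropped_loci),
        dropped_loci=dropped_loci,
        n_samples_in=matrix.n_samples,
        n_samples_dropped=len(dropped_samples),
        dropped_samples=dropped_samples,
    )
    return out, report


def coded_frame(
    matrix: GenotypeMatrix,
    retained_loci: list[str],
    authentic_lines: list[str],
) -> pd.DataFrame:
    """Recode retained polymorphic loci × authentic lines to {A, B, -}.

    A = parent-1 call, B = parent-2 call, "-" = non-parental or missing.
    Raises if a retained locus has an untypeable (MISSING) parental call.
    """
    untypeable = set(matrix.untypeable_loci) & set(retained_loci)
    if untypeable:
        raise ValueError(f"retained loci with untypeable parents: {sorted(untypeable)}")
    block = matrix.calls.loc[retained_loci, authentic_lines].to_numpy(dtype=object)
    p1 = matrix.calls.loc[retained_loci, matrix.parent1].to_numpy(dtype=object)
    p2 = matrix.calls.loc[retained_loci, matrix.parent2].to_numpy(dtype=object)
    out = np.full(block.shape, "-", dtype=object)
    out[block == p1[:, None]] = "A"
    out[block == p2[:, None]] = "B"
    return pd.DataFrame(out, index=pd.Index(retained_loci, name="locus_id"), columns=authentic_lines)


def write_coded(
    matrix: GenotypeMatrix,
    retained_loci: list[str],
    authentic_lines: list[str],
    path,
    delimiter: str = "\t",
) -> None:
    coded_frame(matrix, retained_loci, authentic_lines).to_csv(
        path, sep=delimiter, lineterminator="\n"
    )


def write_rqtl_csv(
    matrix: GenotypeMatrix,
    retained_loci: list[str],
    authentic_lines: list[str],
    path,
    phenotype_name: str = "pheno",
) -> None:
    """Rotated R/qtl "csv" format: individuals as rows, markers as columns,
    a placeholder phenotype column first, and a chromosome row of "1"s
    (real assignments come from mapping, downstream of this tool)."""
    coded = coded_frame(matrix, retained_loci, authentic_lines)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(phenotype_name + "," + ",".join(coded.index) + "\n")
        fh.write("," + ",".join(["1"] * len(coded.index)) + "\n")
        for sample in coded.columns:
            fh.write("," + ",".join(coded[sample]) + "\n")
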