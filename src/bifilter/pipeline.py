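"""Orchestration of the full bi-filtering workflow.

Stage order (fixed): array-level prefilter -> monomorphic/polymorphic split
on parental calls -> line filtering on monomorphic loci -> locus PNPG and
classification over the authentic lines only -> detection-error report ->
coded export of retained loci x authentic lines.  Line filtering strictly
precedes locus classification: contaminated lines inflate locus PNPG, so
the reverse order over-flags multi-locus probes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import classify as _classify
from . import io as _io
from . import pnpg as _pnpg
from .classify import ClassifyConfig, SnpClass
from .core import Call
from .matrix import GenotypeMatrix

log = logging.getLogger("bifilter")


@dataclass(frozen=True)
class RunConfig:
    input: str
    parent1: str
    parent2: str
    out_dir: str
    line_threshold: float = 0.05
    locus_threshold: float = 0.05
    alpha: float = 0.05
    min_count: int = 30
    locus_detect_frac: float = 0.80
    sample_call_rate: float = 0.70
    count_nc_as_detected: bool = True
    remove_unclassified: bool = True
    delimiter: str | None = None
    out_delimiter: str = "\t"

    def __post_init__(self) -> None:
        for name in ("line_threshold", "locus_threshold", "alpha",
                     "locus_detect_frac", "sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.parent1 == self.parent2:
            raise ValueError("parents must be distinct samples")


@dataclass
class RunResult:
    manifest: dict
    out_dir: Path
    authentic_lines: list[str] = field(default_factory=list)
    retained_loci: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = config.out_delimiter
    manifest: dict = {
        "input": str(config.input),
        "input_sha256": _sha256(Path(config.input)),
        "config": asdict(config),
        "stages": {},
    }

    matrix = _io.read_matrix(
        config.input, config.parent1, config.parent2, delimiter=config.delimiter
    )
    manifest["stages"]["input"] = {"n_loci": matrix.n_loci, "n_samples": matrix.n_samples}
    log.info("input: %d loci x %d samples", matrix.n_loci, matrix.n_samples)

    matrix, pre_report = _io.prefilter(
        matrix,
        locus_detect_frac=config.locus_detect_frac,
        sample_call_rate=config.sample_call_rate,
        count_nc_as_detected=config.count_nc_as_detected,
    )
    manifest["stages"]["prefilter"] = {
        "n_loci_dropped": pre_report.n_loci_dropped,
        "n_samples_dropped": pre_report.n_samples_dropped,
        "n_loci": matrix.n_loci,
        "n_samples": matrix.n_samples,
    }
    log.info(
        "prefilter: dropped %d loci, %d samples",
        pre_report.n_loci_dropped,
        pre_report.n_samples_dropped,
    )

    mono = matrix.monomorphic_loci
    poly = matrix.polymorphic_loci
    untypeable = matrix.untypeable_loci
    assert len(mono) + len(poly) + len(untypeable) == matrix.n_loci
    manifest["stages"]["split"] = {
        "n_monomorphic": len(mono),
        "n_polymorphic": len(poly),
        "n_untypeable": len(untypeable),
    }
    if untypeable:
        _pd_series(untypeable, "locus_id").to_csv(out / "untypeable_loci.tsv", sep=sep, index=False)

    # --- line filter on monomorphic loci -------------------------------
    line_records = _pnpg.line_report(matrix, mono, threshold=config.line_threshold)
    kept_lines, removed_lines = _pnpg.filter_lines(line_records, config.line_threshold)
    authentic = [r.sample_id for r in kept_lines]
    _pnpg.line_frame(line_records).to_csv(out / "line_report.tsv", sep=sep, index=False)
    gap = [r for r in kept_lines if 0.03 <= r.pnpg < config.line_threshold]
    manifest["stages"]["line_filter"] = {
        "n_lines": len(line_records),
        "n_authentic": len(kept_lines),
        "n_removed": len(removed_lines),
        "n_kept_in_0.03_to_threshold": len(gap),
        "mean_pnpg_before": _mean([r.pnpg for r in line_records]),
        "mean_pnpg_after": _mean([r.pnpg for r in kept_lines]),
    }
    log.info("line filter: removed %d of %d lines", len(removed_lines), len(line_records))

    # --- monomorphic locus reliability + error report ------------------
    mono_records = _pnpg.locus_report(matrix, mono, authentic, threshold=config.locus_threshold)
    reliable_mono = [r.locus_id for r in mono_records if r.reliable]
    err = _pnpg.error_report(matrix, reliable_mono, authentic)
    err.table.to_csv(out / "error_report.tsv", sep=sep, index=False)
    manifest["stages"]["error_report"] = {
        "n_mono_unreliable": len(mono) - len(reliable_mono),
        "overall_pnpg": err.overall_pnpg,
    }

    # --- polymorphic locus PNPG + classification -----------------------
    cconf = ClassifyConfig(
        locus_threshold=config.locus_threshold, alpha=config.alpha, min_count=config.min_count
    )
    classifications = []
    if poly:
        poly_records = _pnpg.locus_report(matrix, poly, authentic, threshold=config.locus_threshold)
        _pnpg.locus_frame(poly_records).to_csv(out / "locus_report.tsv", sep=sep, index=False)
        block = matrix.calls.loc[poly, authentic]
        for rec in poly_records:
            pair = matrix.parent_pair(rec.locus_id)
            counts_raw = Counter(block.loc[rec.locus_id])
            counts = {Call(t): n for t, n in counts_raw.items() if t != Call.MISSING.value}
            classifications.append(
                _classify.classify_locus(rec.locus_id, pair, counts, rec.pnpg, cconf)
            )
        _classify.classification_frame(classifications).to_csv(
            out / "classification_report.tsv", sep=sep, index=False
        )
    retained, removed = _classify.filter_loci(classifications, config.remove_unclassified)
    retained_ids = [c.locus_id for c in retained]
    assert len(retained) + len(removed) == len(poly)
    class_counts = Counter(c.snp_class.value for c in classifications)
    manifest["stages"]["classification"] = {
        "n_polymorphic": len(poly),
        "n_retained": len(retained),
        "n_removed": len(removed),
        "by_class": dict(sorted(class_counts.items())),
        "pooled_nc_chi2": _jsonable(_classify.pooled_nc_test(classifications)),
    }
    log.info(
        "classification: retained %d / %d polymorphic loci (%s)",
        len(retained),
        len(poly),
        dict(class_counts),
    )

    # --- coded export ---------------------------------------------------
    if retained_ids:
        _io.write_coded(matrix, retained_ids, authentic, out / "coded_matrix.tsv", delimiter=sep)
        _io.write_rqtl_csv(matrix, retained_ids, authentic, out / "coded_rqtl.csv")
    else:
        log.warning("no polymorphic loci retained; coded matrix is empty")
        _io.write_coded(matrix, [], authentic, out / "coded_matrix.tsv", delimiter=sep)
    manifest["stages"]["export"] = {"n_loci": len(retained_ids), "n_lines": len(authentic)}

    with open(out / "manifest.json", "w", encoding="ascii") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(manifest, out, authentic, retained_ids)


def _mean(xs):
    return float(sum(xs) / len(xs)) if xs else float("nan")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float):
        return float(obj)
    return obj


def _pd_series(values, name):
    import pandas as pd

    return pd.Series(list(values), name=name)
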