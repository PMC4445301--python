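"""Synthetic DH-population generator with ground truth.

Emulates a biparental doubled-haploid population genotyped on a polyploid
SNP array: each locus is a one- or two-locus probe (the two-locus cases
carrying homoeologous cross-hybridisation and null alleles), progeny
inherit one parental allele per underlying locus independently, and the
observed call is the signal superposition.  On top of the clean signal the
generator injects (i) contaminated lines — cell-wise replacement with the
superposed call of a third "foreign parent" genome, approximating
mechanical or biological sample contamination, (ii) a symmetric per-call
error (a call becomes one of the other three observed states), and
(iii) missing data.  Every locus keeps its true class and every line its
authenticity label, so filters and classifiers can be scored exactly.

Defaults mirror the study design the method targets: 190 DH lines of which
11 are contaminated at fraction 0.5, 1,000 monomorphic loci whose parental
class composition (AA : AB : BB : NC = 1317 : 16 : 1441 : 574) matches a
real rapeseed array, 400 polymorphic loci of mixed classes, a per-call
error rate of 1.6e-3 and 2% missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import SnpClass, enumerate_expectations
from .core import Allele, AlleleState, Call
from .matrix import GenotypeMatrix

# integer codes used on the fast path
_ALLELE_CODE = {Allele.A: 0, Allele.B: 1, Allele.NULL: 2, Allele.ABSENT: 3}
_CALL_TOKENS = np.array(["AA", "AB", "BB", "NC"], dtype=object)

#: default monomorphic parental-class composition (AA, AB, BB, NC)
MONO_CLASS_WEIGHTS = (1317, 16, 1441, 574)

_MONO_STATES = {
    Call.AA: AlleleState(Allele.A, Allele.ABSENT),
    Call.AB: AlleleState(Allele.A, Allele.B),
    Call.BB: AlleleState(Allele.B, Allele.ABSENT),
    Call.NC: AlleleState(Allele.NULL, Allele.ABSENT),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_lines: int = 190
    n_monomorphic: int = 1000
    n_simple: int = 60
    n_shemi: int = 220
    n_mhemi: int = 80
    n_pseudo: int = 40
    contamination: tuple[tuple[int, float], ...] = tuple((i, 0.5) for i in range(11))
    call_error_rate: float = 0.0016
    missing_rate: float = 0.02
    mono_class_weights: tuple[float, float, float, float] = MONO_CLASS_WEIGHTS

    def __post_init__(self) -> None:
        for name in ("call_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for n in ("n_lines", "n_monomorphic", "n_simple", "n_shemi", "n_mhemi", "n_pseudo"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be non-negative")
        for idx, frac in self.contamination:
            if not 0 <= idx < self.n_lines:
                raise ValueError(f"contaminated line index {idx} out of range")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"contamination fraction {frac} out of [0, 1]")


@dataclass
class SimTruth:
    """Ground truth: per-locus class/states, per-line authenticity, pre-noise calls.

    ``pre_noise`` holds the progeny calls after contamination but before
    call error and missingness — contamination is a property of the line,
    error and missingness of the assay.
    """

    loci: pd.DataFrame
    lines: pd.DataFrame
    pre_noise: pd.DataFrame

    def true_classes(self) -> dict[str, str]:
        return dict(zip(self.loci["locus_id"], self.loci["true_class"]))


def _class_pools():
    """Representative parental state pairs per SNP class, from the model enumeration."""
    pools: dict[SnpClass, list] = {c: [] for c in SnpClass}
    for g in enumerate_expectations():
        if g.snp_class is SnpClass.SIMPLE:
            states = [sp for sp in g.parent_states if sp[0].single_locus and sp[1].single_locus]
        else:
            states = list(g.parent_states)
        for sp in states:
            pools[g.snp_class].append((g, sp))
    return pools


def _superpose_codes(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    has_a = (a1 == 0) | (a2 == 0)
    has_b = (a1 == 1) | (a2 == 1)
    return np.where(has_a & has_b, 1, np.where(has_a, 0, np.where(has_b, 2, 3))).astype(np.int8)


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a call matrix (parents P1, P2 + DH lines) and its ground truth.

    Deterministic under a fixed seed.  Parents are emitted noise-free (the
    workflow assumes curated parental calls); progeny cells get
    contamination, then symmetric call error, then missingness.
    """
    rng = np.random.default_rng(config.seed)
    pools = _class_pools()

    locus_rows = []
    p1l1, p1l2, p2l1, p2l2 = [], [], [], []

    def push(locus_id, category, true_class, group_id, s1: AlleleState, s2: AlleleState, npg_freq):
        p1l1.append(_ALLELE_CODE[s1.locus1])
        p1l2.append(_ALLELE_CODE[s1.locus2])
        p2l1.append(_ALLELE_CODE[s2.locus1])
        p2l2.append(_ALLELE_CODE[s2.locus2])
        locus_rows.append(
            {
                "locus_id": locus_id,
                "category": category,
                "true_class": true_class,
                "group_id": group_id,
                "p1_state": str(s1),
                "p2_state": str(s2),
                "expected_npg_freq": float(npg_freq),
            }
        )

    weights = np.asarray(config.mono_class_weights, dtype=float)
    mono_calls = rng.choice(4, size=config.n_monomorphic, p=weights / weights.sum())
    mono_call_order = (Call.AA, Call.AB, Call.BB, Call.NC)
    for i, ci in enumerate(mono_calls):
        s = _MONO_STATES[mono_call_order[ci]]
        push(f"mono{i + 1:05d}", "monomorphic", "Monomorphic", 0, s, s, 0.0)

    class_counts = (
        (SnpClass.SIMPLE, config.n_simple),
        (SnpClass.S_HEMI, config.n_shemi),
        (SnpClass.M_HEMI, config.n_mhemi),
        (SnpClass.PSEUDO_SIMPLE, config.n_pseudo),
    )
    snp_idx = 0
    for cls, n in class_counts:
        pool = pools[cls]
        picks = rng.integers(0, len(pool), size=n)
        flips = rng.integers(0, 2, size=n)
        for k in range(n):
            snp_idx += 1
            group, (s1, s2) = pool[picks[k]]
            if flips[k]:
                s1, s2 = s2, s1
            push(f"snp{snp_idx + 0:05d}", "polymorphic", cls.value, group.group_id,
                 s1, s2, group.npg_frequency)

    n_loci = len(locus_rows)
    n_lines = config.n_lines
    P1L1 = np.array(p1l1, dtype=np.int8)
    P1L2 = np.array(p1l2, dtype=np.int8)
    P2L1 = np.array(p2l1, dtype=np.int8)
    P2L2 = np.array(p2l2, dtype=np.int8)

    parent1_codes = _superpose_codes(P1L1, P1L2)
    parent2_codes = _superpose_codes(P2L1, P2L2)

    # progeny: one parental allele per underlying locus, independently
    pick1 = rng.integers(0, 2, size=(n_loci, n_lines), dtype=np.int8)
    pick2 = rng.integers(0, 2, size=(n_loci, n_lines), dtype=np.int8)
    a1 = np.where(pick1 == 0, P1L1[:, None], P2L1[:, None])
    a2 = np.where(pick2 == 0, P1L2[:, None], P2L2[:, None])
    codes = _superpose_codes(a1, a2)

    # foreign parent genome (shared by all contaminated lines)
    f1 = rng.integers(0, 3, size=n_loci, dtype=np.int8)
    f2 = np.where(P1L2 == 3, np.int8(3), rng.integers(0, 3, size=n_loci, dtype=np.int8))
    foreign_codes = _superpose_codes(f1, f2)

    contamination_frac = np.zeros(n_lines)
    for idx, frac in config.contamination:
        contamination_frac[idx] = frac
        mask = rng.random(n_loci) < frac
        codes[mask, idx] = foreign_codes[mask]

    pre_noise = codes.copy()

    if config.call_error_rate > 0:
        err = rng.random((n_loci, n_lines)) < config.call_error_rate
        shift = rng.integers(1, 4, size=(n_loci, n_lines), dtype=np.int8)
        codes = np.where(err, (codes + shift) % 4, codes).astype(np.int8)

    missing = (
        rng.random((n_loci, n_lines)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((n_loci, n_lines), dtype=bool)
    )

    locus_ids = [r["locus_id"] for r in locus_rows]
    line_ids = [f"DH{i + 1:03d}" for i in range(n_lines)]
    cells = _CALL_TOKENS[codes]
    cells[missing] = Call.MISSING.value

    df = pd.DataFrame(cells, index=locus_ids, columns=line_ids)
    df.insert(0, "P2", _CALL_TOKENS[parent2_codes])
    df.insert(0, "P1", _CALL_TOKENS[parent1_codes])
    df.index.name = "locus_id"
    matrix = GenotypeMatrix(df, "P1", "P2")

    loci_df = pd.DataFrame(locus_rows)
    loci_df["parent1_call"] = _CALL_TOKENS[parent1_codes]
    loci_df["parent2_call"] = _CALL_TOKENS[parent2_codes]
    loci_df["foreign_call"] = _CALL_TOKENS[foreign_codes]
    lines_df = pd.DataFrame(
        {
            "sample_id": line_ids,
            "authentic": contamination_frac == 0.0,
            "contamination_fraction": contamination_frac,
        }
    )
    pre_df = pd.DataFrame(_CALL_TOKENS[pre_noise], index=locus_ids, columns=line_ids)
    return matrix, SimTruth(loci_df, lines_df, pre_df)


def foreign_npg_rate(truth: SimTruth, monomorphic_only: bool = True) -> float:
    """Fraction of (monomorphic) loci where the realised foreign call is non-parental.

    A line contaminated at fraction f has expected PNPG ~ f × this rate on
    monomorphic loci (before call error), since replaced cells carry the
    foreign call and untouched cells the parental one.
    """
    loci = truth.loci
    if monomorphic_only:
        loci = loci[loci["category"] == "monomorphic"]
    npg = (loci["foreign_call"] != loci["parent1_call"]) & (
        loci["foreign_call"] != loci["parent2_call"]
    )
    return float(npg.mean())


def truth_score(
    locus_classes: dict[str, str],
    line_authentic: dict[str, bool],
    truth: SimTruth,
) -> dict:
    """Confusion summary: per-class precision/recall for loci, line sensitivity/specificity.

    ``locus_classes`` maps polymorphic locus id to the assigned class name,
    ``line_authentic`` maps DH sample id to the filter's verdict.
    Line sensitivity is the fraction of contaminated lines flagged
    unauthentic; specificity the fraction of authentic lines kept.
    """
    poly = truth.loci[truth.loci["category"] == "polymorphic"]
    missing = set(poly["locus_id"]) - set(locus_classes)
    if missing:
        raise ValueError(f"decisions missing for {len(missing)} polymorphic loci")
    per_class: dict[str, dict] = {}
    true_by_id = dict(zip(poly["locus_id"], poly["true_class"]))
    classes = sorted(set(true_by_id.values()) | set(locus_classes[l] for l in true_by_id))
    for cls in classes:
        tp = sum(1 for l, t in true_by_id.items() if t == cls and locus_classes[l] == cls)
        fp = sum(1 for l, t in true_by_id.items() if t != cls and locus_classes[l] == cls)
        fn = sum(1 for l, t in true_by_id.items() if t == cls and locus_classes[l] != cls)
        per_class[cls] = {
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
            "n_true": tp + fn,
        }

    lines = truth.lines
    missing_lines = set(lines["sample_id"]) - set(line_authentic)
    if missing_lines:
        raise ValueError(f"decisions missing for {len(missing_lines)} lines")
    contaminated = set(lines.loc[~lines["authentic"], "sample_id"])
    authentic = set(lines.loc[lines["authentic"], "sample_id"])
    flagged = {s for s, ok in line_authentic.items() if not ok}
    sens = len(contaminated & flagged) / len(contaminated) if contaminated else float("nan")
    spec = len(authentic - flagged) / len(authentic) if authentic else float("nan")
    return {
        "locus_classification": per_class,
        "line_filter": {
            "sensitivity": sens,
            "specificity": spec,
            "n_contaminated": len(contaminated),
            "n_flagged": len(flagged),
        },
    }


def write_fixture(matrix: GenotypeMatrix, truth: SimTruth, out_dir) -> None:
    """Write the matrix in the standard dialect plus TSV truth sidecars."""
    from pathlib import Path

    from .io import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(matrix, out / "matrix.tsv")
    truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    truth.lines.to_csv(out / "truth_lines.tsv", sep="\t", index=False)
    truth.pre_noise.to_csv(out / "truth_pre_noise.tsv", sep="\t")
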