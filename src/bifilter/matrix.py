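"""The loci × samples genotype-call matrix container.

Internally a pandas DataFrame of call-token strings (``AA AB BB NC -``),
rows indexed by locus id, columns by sample id, with the two parental
columns designated by name.  All heavier computation (PNPG, reports) works
on the underlying numpy string array; this class only enforces shape and
vocabulary invariants and provides the monomorphic/polymorphic split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Call, ParentPair

_VOCAB = frozenset(c.value for c in Call)


@dataclass
class GenotypeMatrix:
    calls: pd.DataFrame
    parent1: str
    parent2: str
    _parent_pairs: dict[str, ParentPair] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise ValueError("the two parent samples must be distinct")
        for p in (self.parent1, self.parent2):
            if p not in self.calls.columns:
                raise ValueError(f"parent sample {p!r} not among matrix columns")
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate locus identifiers: {dups}")
        if self.calls.columns.has_duplicates:
            dups = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        bad = set(np.unique(self.calls.to_numpy(dtype=object))) - _VOCAB
        if bad:
            raise ValueError(f"unknown call tokens: {sorted(bad)}")

    # -- basic views -------------------------------------------------------

    @property
    def loci(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def progeny(self) -> list[str]:
        return [s for s in self.calls.columns if s not in (self.parent1, self.parent2)]

    @property
    def n_loci(self) -> int:
        return len(self.calls.index)

    @property
    def n_samples(self) -> int:
        return len(self.calls.columns)

    def parent_pair(self, locus_id: str) -> ParentPair:
        pair = self._parent_pairs.get(locus_id)
        if pair is None:
            row = self.calls.loc[locus_id]
            pair = ParentPair(Call(row[self.parent1]), Call(row[self.parent2]))
            self._parent_pairs[locus_id] = pair
        return pair

    # -- locus partitions --------------------------------------------------

    def _parent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        p1 = self.calls[self.parent1].to_numpy(dtype=object)
        p2 = self.calls[self.parent2].to_numpy(dtype=object)
        return p1, p2

    @property
    def untypeable_loci(self) -> list[str]:
        """Loci where a parental call is MISSING (set aside, never dropped silently)."""
        p1, p2 = self._parent_arrays()
        mask = (p1 == Call.MISSING.value) | (p2 == Call.MISSING.value)
        return list(self.calls.index[mask])

    @property
    def monomorphic_loci(self) -> list[str]:
        p1, p2 = self._parent_arrays()
        mask = (p1 == p2) & (p1 != Call.MISSING.value)
        return list(self.calls.index[mask])

    @property
    def polymorphic_loci(self) -> list[str]:
        p1, p2 = self._parent_arrays()
        mask = (p1 != p2) & (p1 != Call.MISSING.value) & (p2 != Call.MISSING.value)
        return list(self.calls.index[mask])

    # -- subsetting --------------------------------------------------------

    def subset(self, loci=None, samples=None) -> "GenotypeMatrix":
        """Restricted copy; parental columns are always retained."""
        df = self.calls
        if loci is not None:
            df = df.loc[list(loci)]
        if samples is not None:
            keep = [s for s in df.columns if s in set(samples) or s in (self.parent1, self.parent2)]
            df = df[keep]
        return GenotypeMatrix(df.copy(), self.parent1, self.parent2)
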