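"""Shared domain types for the lncRNA/mRNA array pipeline.

All expression values are log2 intensities. Samples belong to one of two
groups, ``case`` (patients) and ``control``; every statistical operation
requires at least two samples per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
GROUPS = (CONTROL, CASE)

LNCRNA = "lncRNA"
MRNA = "mRNA"


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of log2 intensities with group labels.

    ``values`` is indexed by probe id (rows) and sample id (columns);
    ``groups`` maps every sample id to ``case`` or ``control``. Missing or
    non-finite values are rejected at construction, never imputed.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe id(s): {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"sample(s) without group label: {missing}")
        bad_labels = {g for g in self.groups.values() if g not in GROUPS}
        if bad_labels:
            raise ValidationError(
                f"group labels must be one of {GROUPS}, got {sorted(bad_labels)}"
            )
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at probe {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        self.values = v.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def require_two_per_group(self) -> None:
        for g in GROUPS:
            n = len(self.samples_in(g))
            if n < 2:
                raise ValidationError(
                    f"group {g!r} has {n} sample(s); statistics need >= 2"
                )

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise ValidationError(f"unknown probe id(s): {missing}")
        return ExpressionMatrix(self.values.loc[list(probe_ids)], dict(self.groups))


@dataclass
class ProbeAnnotation:
    """Per-probe metadata: molecule class, gene symbol, optional coordinates.

    Coordinates are 1-based inclusive and carried as metadata only.
    """

    table: pd.DataFrame  # columns: probe_id, molecule_class, gene_symbol, chrom, start, end

    REQUIRED = ("probe_id", "molecule_class")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        for col in ("gene_symbol", "chrom", "start", "end"):
            if col not in t.columns:
                t = t.assign(**{col: None})
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe id(s) in annotation: {dups}")
        bad = set(t["molecule_class"]) - {LNCRNA, MRNA}
        if bad:
            raise ValidationError(f"unknown molecule class(es): {sorted(bad)}")
        has_coord = t["start"].notna() & t["end"].notna()
        if (t.loc[has_coord, "start"].astype(float) > t.loc[has_coord, "end"].astype(float)).any():
            raise ValidationError("coordinate start > end for some probe(s)")
        self.table = t.reset_index(drop=True)

    def probes_of_class(self, molecule_class: str) -> list[str]:
        t = self.table
        return t.loc[t["molecule_class"] == molecule_class, "probe_id"].tolist()

    def symbol_map(self) -> dict[str, str]:
        """probe_id -> gene symbol, for annotated probes only."""
        t = self.table
        has = t["gene_symbol"].notna() & (t["gene_symbol"] != "")
        return dict(zip(t.loc[has, "probe_id"], t.loc[has, "gene_symbol"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term id -> (description, member symbols).

    The universe is the union of all members; used both for functional terms
    and for transcription-factor target lists.
    """

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_desc, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _desc, members in self.sets.values():
            out |= members
        return frozenset(out)

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def term_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class QPCRRecord:
    """Ct replicates for one sample: target gene and endogenous reference."""

    sample_id: str
    group: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, reps in (("target", self.target_ct), ("reference", self.reference_ct)):
            reps = tuple(float(x) for x in reps)
            if len(reps) < 1:
                raise ValidationError(f"{name} Ct needs >= 1 replicate")
            if not all(np.isfinite(reps)) or any(x <= 0 for x in reps):
                raise ValidationError(f"{name} Ct values must be positive and finite")
        self.target_ct = tuple(float(x) for x in self.target_ct)
        self.reference_ct = tuple(float(x) for x in self.reference_ct)
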