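"""Core domain types: clones, sample metadata, and repertoires.

A *clonotype* (clone) is a unique rearranged CDR3 sequence together with
its V/J gene context; its abundance proxies the size of the descendant
T-cell population in the biopsy.  A :class:`Repertoire` is one sample's
collapsed clone table plus sample metadata, and is the unit every
statistic in this package operates on.

Clone identity is deliberately two-headed:

``nt_vj``
    CDR3 nucleotide sequence + V gene + J gene.  The vendor-style
    clonotype definition; used for within-cohort counting and
    within-patient paired comparisons.
``aa_only``
    CDR3 amino-acid sequence alone.  Convergent recombination produces
    the same amino-acid junction from different nucleotide
    rearrangements, so this is the biologically meaningful unit for
    cross-individual (public-clone) sharing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Chain",
    "TissueGroup",
    "SourceMaterial",
    "KeyMode",
    "CloneRecord",
    "SampleMetadata",
    "Repertoire",
    "CLONE_COLUMNS",
    "STOP_SYMBOL",
    "FREQ_TOL",
]

#: symbol marking a stop codon in a translated junction
STOP_SYMBOL = "*"

#: tolerance on the clone-frequency closure invariant (sum to 1)
FREQ_TOL = 1e-6

#: canonical column order of the clone table held by a Repertoire
CLONE_COLUMNS = [
    "cdr3_nt",
    "cdr3_aa",
    "v_gene",
    "d_gene",
    "j_gene",
    "count",
    "frequency",
    "productive",
]


class Chain(str, enum.Enum):
    """Sequenced TCR chain: β (from gDNA) or γ (from cDNA)."""

    TRB = "TRB"
    TRG = "TRG"


class TissueGroup(str, enum.Enum):
    """Biopsy group: healthy skin, or psoriatic non-lesional / lesional."""

    NORMAL = "normal"
    NON_LESIONAL = "non_lesional"
    LESIONAL = "lesional"


class SourceMaterial(str, enum.Enum):
    gDNA = "gDNA"
    cDNA = "cDNA"


class KeyMode(str, enum.Enum):
    """Clone identity definition used when comparing or collapsing."""

    NT_VJ = "nt_vj"
    AA_ONLY = "aa_only"


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype row of a sample's clone table.

    ``count`` is the template count when the assay provides one, else the
    read count; ``frequency`` is always count over the sample total, the
    ``P_i`` entering the entropy calculation.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int
    frequency: float
    productive: bool
    d_gene: str = ""

    def validate(self) -> None:
        if not self.cdr3_nt:
            raise ValidationError("clone has empty CDR3 nucleotide sequence")
        if self.count < 1:
            raise ValidationError(f"clone count must be >= 1, got {self.count}")
        if not self.frequency > 0:
            raise ValidationError(
                f"clone frequency must be > 0, got {self.frequency}"
            )
        if self.productive:
            if not self.cdr3_aa:
                raise ValidationError("productive clone with empty CDR3 amino-acid sequence")
            if STOP_SYMBOL in self.cdr3_aa:
                raise ValidationError("productive clone contains a stop-codon symbol")


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one sequenced skin sample."""

    sample_id: str
    patient_id: str
    group: TissueGroup
    chain: Chain
    source_material: SourceMaterial | None = None

    def __post_init__(self) -> None:
        # normalise plain strings to enums so constructors stay forgiving
        object.__setattr__(self, "group", TissueGroup(self.group))
        object.__setattr__(self, "chain", Chain(self.chain))
        if self.source_material is not None:
            object.__setattr__(
                self, "source_material", SourceMaterial(self.source_material)
            )


@dataclass
class Repertoire:
    """One sample's collapsed clone table plus its metadata.

    The clone table is a :class:`pandas.DataFrame` with columns
    :data:`CLONE_COLUMNS`, one row per unique ``nt_vj`` clonotype,
    sorted by descending count (stable, so the input order of
    equal-count clones is preserved).
    """

    metadata: SampleMetadata
    clones: pd.DataFrame = field(repr=False)

    # -- basic accessors -------------------------------------------------

    @property
    def n_unique(self) -> int:
        return len(self.clones)

    @property
    def total_count(self) -> int:
        return int(self.clones["count"].sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.clones["frequency"].to_numpy(dtype=float)

    def records(self) -> Iterator[CloneRecord]:
        for row in self.clones[CLONE_COLUMNS].to_dict("records"):
            yield CloneRecord(
                cdr3_nt=row["cdr3_nt"],
                cdr3_aa=row["cdr3_aa"],
                v_gene=row["v_gene"],
                d_gene=row["d_gene"],
                j_gene=row["j_gene"],
                count=int(row["count"]),
                frequency=float(row["frequency"]),
                productive=bool(row["productive"]),
            )

    # -- identity keys ---------------------------------------------------

    def keys(self, mode: KeyMode | str = KeyMode.NT_VJ) -> list[tuple]:
        """Identity keys of all clones, in table order."""
        mode = KeyMode(mode)
        if mode is KeyMode.NT_VJ:
            return list(
                zip(
                    ("nt",) * len(self.clones),
                    self.clones["cdr3_nt"],
                    self.clones["v_gene"],
                    self.clones["j_gene"],
                )
            )
        empties = ~self.clones["cdr3_aa"].astype(bool)
        if empties.any():
            raise ValidationError(
                f"sample {self.metadata.sample_id}: cannot key "
                f"{int(empties.sum())} clone(s) with empty CDR3 amino-acid "
                "sequence by aa_only; filter to productive clones first"
            )
        return list(zip(("aa",) * len(self.clones), self.clones["cdr3_aa"]))

    def key_set(self, mode: KeyMode | str = KeyMode.NT_VJ) -> set[tuple]:
        return set(self.keys(mode))

    def key_frequencies(self, mode: KeyMode | str = KeyMode.NT_VJ) -> dict[tuple, float]:
        """Mapping identity key -> summed frequency (aa_only keys can
        aggregate several nucleotide variants)."""
        out: dict[tuple, float] = {}
        for key, f in zip(self.keys(mode), self.frequencies):
            out[key] = out.get(key, 0.0) + float(f)
        return out

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if len(self.clones) == 0:
            raise ValidationError(
                f"sample {self.metadata.sample_id}: repertoire has no clones"
            )
        missing = [c for c in CLONE_COLUMNS if c not in self.clones.columns]
        if missing:
            raise ValidationError(f"clone table missing columns: {missing}")
        if (self.clones["count"] < 1).any():
            raise ValidationError("clone table contains non-positive counts")
        total = self.clones["frequency"].sum()
        if abs(total - 1.0) > FREQ_TOL:
            raise ValidationError(
                f"clone frequencies sum to {total!r}, expected 1 ± {FREQ_TOL}"
            )
        keys = self.keys(KeyMode.NT_VJ)
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate nt_vj clone keys; table not collapsed")

    def with_metadata(self, **kwargs) -> "Repertoire":
        return Repertoire(replace(self.metadata, **kwargs), self.clones.copy())
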