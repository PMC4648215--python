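"""Cross-sample repertoire comparisons.

Covers four analyses:

* pairwise overlap scores between repertoires (default: Jaccard index
  on unique clone keys — shared / union, symmetric, in [0, 1]);
* pooling of all pairwise scores into comparison groups (NN, N-NL,
  N-LS, NL-NL, NL-LS, LS-LS) with the within-patient exclusion rule:
  a non-lesional vs lesional comparison of the *same* patient is
  flagged and left out of the pooled NL-LS group, since within-patient
  sharing would artificially inflate the between-patient signal;
* within-patient paired non-lesional / lesional clone classification
  (unique-to-NL, unique-to-LS, shared, with frequencies as percent of
  each sample's total);
* public-clone detection: clone keys present in every sample of a
  scope, by default at amino-acid identity, since convergent
  recombination makes the amino-acid junction the meaningful
  cross-individual unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ComparisonError, PairingError, ValidationError
from .types import KeyMode, Repertoire, TissueGroup

__all__ = [
    "OverlapRecord",
    "overlap_score",
    "pool_overlaps",
    "overlap_table",
    "PairedComparison",
    "paired_comparison",
    "PublicCloneReport",
    "common_clones",
    "COMPARISON_GROUPS",
]

_GROUP_ABBREV = {
    TissueGroup.NORMAL: "N",
    TissueGroup.NON_LESIONAL: "NL",
    TissueGroup.LESIONAL: "LS",
}

#: canonical comparison-group labels, in pooling order
COMPARISON_GROUPS = ["NN", "N-NL", "N-LS", "NL-NL", "NL-LS", "LS-LS"]

_GROUP_ORDER = [TissueGroup.NORMAL, TissueGroup.NON_LESIONAL, TissueGroup.LESIONAL]


def comparison_group(a: TissueGroup, b: TissueGroup) -> str:
    """Canonical label for an unordered pair of tissue groups."""
    pair = sorted((a, b), key=_GROUP_ORDER.index)
    if pair[0] is TissueGroup.NORMAL and pair[1] is TissueGroup.NORMAL:
        return "NN"
    return f"{_GROUP_ABBREV[pair[0]]}-{_GROUP_ABBREV[pair[1]]}"


@dataclass(frozen=True)
class OverlapRecord:
    sample_a: str
    sample_b: str
    n_shared: int
    score: float
    comparison_group: str
    same_patient: bool
    excluded: bool = False


def _score(
    keys_a: set, keys_b: set, rep_a: Repertoire, rep_b: Repertoire,
    key_mode: KeyMode, norm: str,
) -> tuple[int, float]:
    shared = keys_a & keys_b
    n_shared = len(shared)
    if norm == "jaccard":
        union = len(keys_a | keys_b)
        return n_shared, n_shared / union if union else 0.0
    if norm == "min":
        m = min(len(keys_a), len(keys_b))
        return n_shared, n_shared / m if m else 0.0
    if norm == "morisita":
        # Morisita-Horn on clone frequencies over the union of keys
        fa = rep_a.key_frequencies(key_mode)
        fb = rep_b.key_frequencies(key_mode)
        keys = keys_a | keys_b
        x = np.array([fa.get(k, 0.0) for k in keys])
        y = np.array([fb.get(k, 0.0) for k in keys])
        denom = ((x ** 2).sum() + (y ** 2).sum())
        return n_shared, float(2 * (x * y).sum() / denom) if denom else 0.0
    raise ValidationError(f"unknown overlap normalization {norm!r}")


def overlap_score(
    rep_a: Repertoire,
    rep_b: Repertoire,
    key_mode: KeyMode | str = KeyMode.AA_ONLY,
    norm: str = "jaccard",
) -> OverlapRecord:
    """Pairwise repertoire overlap; symmetric in its arguments."""
    if rep_a.metadata.chain is not rep_b.metadata.chain:
        raise ComparisonError(
            f"cannot compare chains {rep_a.metadata.chain.value} and "
            f"{rep_b.metadata.chain.value}"
        )
    key_mode = KeyMode(key_mode)
    n_shared, score = _score(
        rep_a.key_set(key_mode), rep_b.key_set(key_mode), rep_a, rep_b,
        key_mode, norm,
    )
    group = comparison_group(rep_a.metadata.group, rep_b.metadata.group)
    same_patient = rep_a.metadata.patient_id == rep_b.metadata.patient_id
    return OverlapRecord(
        sample_a=rep_a.metadata.sample_id,
        sample_b=rep_b.metadata.sample_id,
        n_shared=n_shared,
        score=score,
        comparison_group=group,
        same_patient=same_patient,
        excluded=same_patient and group == "NL-LS",
    )


def pool_overlaps(
    cohort: list[Repertoire],
    key_mode: KeyMode | str = KeyMode.AA_ONLY,
    norm: str = "jaccard",
) -> list[OverlapRecord]:
    """All unordered pairwise overlaps within one chain.

    Within-patient NL-LS records are flagged ``excluded``; pooled group
    summaries (and downstream inference) must drop them.
    """
    chains = {rep.metadata.chain for rep in cohort}
    if len(chains) > 1:
        raise ComparisonError("cohort mixes TRB and TRG samples; pool one chain at a time")
    if len(cohort) < 2:
        raise ComparisonError("need at least two samples to compute overlaps")
    return [
        overlap_score(a, b, key_mode=key_mode, norm=norm)
        for a, b in combinations(cohort, 2)
    ]


def overlap_table(records: list[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "n_shared": r.n_shared,
                "score": r.score,
                "comparison_group": r.comparison_group,
                "same_patient": r.same_patient,
                "excluded": r.excluded,
            }
            for r in records
        ]
    )


@dataclass
class PairedComparison:
    """Within-patient NL/LS clone classification.

    Frequencies are percent of each sample's total count, matching the
    percent-of-total-reads axes of a paired clone scatter plot.
    """

    patient_id: str
    key_mode: KeyMode
    unique_nl: pd.DataFrame = field(repr=False)  # key, freq_nl_pct
    unique_ls: pd.DataFrame = field(repr=False)  # key, freq_ls_pct
    shared: pd.DataFrame = field(repr=False)  # key, freq_nl_pct, freq_ls_pct

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unique_nl": len(self.unique_nl),
            "unique_ls": len(self.unique_ls),
            "shared": len(self.shared),
        }


def paired_comparison(
    nl: Repertoire,
    ls: Repertoire,
    key_mode: KeyMode | str = KeyMode.NT_VJ,
) -> PairedComparison:
    """Partition the clone keys of a patient's NL/LS pair into
    unique-to-NL, unique-to-LS, and shared sets."""
    if nl.metadata.patient_id != ls.metadata.patient_id:
        raise PairingError(
            f"samples {nl.metadata.sample_id} and {ls.metadata.sample_id} "
            "belong to different patients"
        )
    if nl.metadata.chain is not ls.metadata.chain:
        raise PairingError("paired samples must be the same chain")
    if (
        nl.metadata.group is not TissueGroup.NON_LESIONAL
        or ls.metadata.group is not TissueGroup.LESIONAL
    ):
        raise PairingError(
            "paired comparison expects a non-lesional and a lesional sample"
        )
    key_mode = KeyMode(key_mode)
    f_nl = nl.key_frequencies(key_mode)
    f_ls = ls.key_frequencies(key_mode)
    shared_keys = sorted(set(f_nl) & set(f_ls))
    nl_only = sorted(set(f_nl) - set(f_ls))
    ls_only = sorted(set(f_ls) - set(f_nl))
    return PairedComparison(
        patient_id=nl.metadata.patient_id,
        key_mode=key_mode,
        unique_nl=pd.DataFrame(
            {"key": nl_only, "freq_nl_pct": [100 * f_nl[k] for k in nl_only]}
        ),
        unique_ls=pd.DataFrame(
            {"key": ls_only, "freq_ls_pct": [100 * f_ls[k] for k in ls_only]}
        ),
        shared=pd.DataFrame(
            {
                "key": shared_keys,
                "freq_nl_pct": [100 * f_nl[k] for k in shared_keys],
                "freq_ls_pct": [100 * f_ls[k] for k in shared_keys],
            }
        ),
    )


@dataclass
class PublicCloneReport:
    """Clone keys present in every sample of a scope, with per-sample
    frequencies (fractions)."""

    sample_ids: list[str]
    key_mode: KeyMode
    clones: pd.DataFrame = field(repr=False)  # key + freq_<sample_id> columns

    @property
    def n_clones(self) -> int:
        return len(self.clones)


def common_clones(
    samples: list[Repertoire],
    key_mode: KeyMode | str = KeyMode.AA_ONLY,
) -> PublicCloneReport:
    """Intersection of clone key sets across all given samples."""
    if not samples:
        raise ComparisonError("need at least one sample")
    if len({rep.metadata.chain for rep in samples}) > 1:
        raise ComparisonError("cannot intersect clones across different chains")
    key_mode = KeyMode(key_mode)
    freq_maps = [rep.key_frequencies(key_mode) for rep in samples]
    keys = set(freq_maps[0])
    for fm in freq_maps[1:]:
        keys &= set(fm)
    keys = sorted(keys)
    table = {"key": keys}
    for rep, fm in zip(samples, freq_maps):
        table[f"freq_{rep.metadata.sample_id}"] = [fm[k] for k in keys]
    return PublicCloneReport(
        sample_ids=[rep.metadata.sample_id for rep in samples],
        key_mode=key_mode,
        clones=pd.DataFrame(table),
    )
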