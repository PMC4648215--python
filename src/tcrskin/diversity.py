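"""Per-repertoire diversity statistics and V/J gene usage.

The repertoire's frequency distribution :math:`P_1..P_N` over its
:math:`N` unique clones is summarised by Shannon entropy

.. math:: H = -\\sum_{i=1}^{N} P_i \\log_2 P_i \\quad \\text{(bits)},

its maximum :math:`H_{max} = \\log_2 N` (attained by a uniform
repertoire), the normalised entropy :math:`H_N = H / H_{max}` (sample
evenness, robust to sequencing depth), and clonality

.. math:: C = 1 - H_N,

which is 0 for a perfectly even (polyclonal) repertoire and 1 when a
single clone makes up the whole sample.  A singleton repertoire
(:math:`N = 1`) has :math:`H_{max} = 0` and an undefined :math:`H_N`;
by convention we assign it clonality 1, the maximal-concentration
limit.

Entropy uses observed clone frequencies as-is; no coverage correction
(Chao/ACE-style) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import filter_productive
from .types import FREQ_TOL, Repertoire

__all__ = [
    "shannon_entropy",
    "clonality",
    "DiversitySummary",
    "summarize_diversity",
    "diversity_table",
    "UsageProfile",
    "vj_usage",
]


def _check_frequencies(frequencies) -> np.ndarray:
    p = np.asarray(frequencies, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("frequency vector must be one-dimensional and non-empty")
    if (p <= 0).any():
        raise ValidationError(
            "frequency vector contains zero or negative entries; "
            "drop zero-count clones upstream"
        )
    if abs(p.sum() - 1.0) > FREQ_TOL:
        raise ValidationError(f"frequencies sum to {p.sum()!r}, expected 1")
    return p


def shannon_entropy(frequencies) -> float:
    """Shannon entropy of a clone-frequency vector, in bits."""
    p = _check_frequencies(frequencies)
    if p.size == 1:
        return 0.0
    return float(stats.entropy(p, base=2))


def clonality(frequencies) -> float:
    """Clonality C = 1 − H / log2(N); 1 for a singleton repertoire."""
    p = _check_frequencies(frequencies)
    n = p.size
    if n == 1:
        return 1.0
    c = 1.0 - shannon_entropy(p) / np.log2(n)
    # guard the algebraic range against floating-point round-off
    return float(min(1.0, max(0.0, c)))


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    n_unique: int
    total_count: int
    entropy: float
    entropy_max: float
    entropy_normalized: float
    clonality: float


def summarize_diversity(rep: Repertoire, productive_only: bool = True) -> DiversitySummary:
    """Full diversity summary of one repertoire.

    With ``productive_only`` (the default) non-productive clones are
    removed and frequencies renormalised before anything is computed.
    """
    rep.validate()
    if productive_only:
        rep = filter_productive(rep)
    p = rep.frequencies
    n = rep.n_unique
    h = shannon_entropy(p)
    h_max = float(np.log2(n))
    c = clonality(p)
    h_n = 1.0 - c
    return DiversitySummary(
        sample_id=rep.metadata.sample_id,
        n_unique=n,
        total_count=rep.total_count,
        entropy=h,
        entropy_max=h_max,
        entropy_normalized=h_n,
        clonality=c,
    )


def diversity_table(
    cohort: list[Repertoire], productive_only: bool = True
) -> pd.DataFrame:
    """One DiversitySummary row per sample, with group/chain metadata."""
    rows = []
    for rep in cohort:
        s = summarize_diversity(rep, productive_only=productive_only)
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": rep.metadata.patient_id,
                "group": rep.metadata.group.value,
                "chain": rep.metadata.chain.value,
                "n_unique": s.n_unique,
                "total_count": s.total_count,
                "entropy": s.entropy,
                "entropy_max": s.entropy_max,
                "entropy_normalized": s.entropy_normalized,
                "clonality": s.clonality,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class UsageProfile:
    sample_id: str
    segment_class: str  # "V" or "J"
    usage: dict[str, float]


def vj_usage(
    rep: Repertoire,
    segment_class: str,
    weighting: str = "by_clone",
) -> UsageProfile:
    """Gene-segment usage profile of one repertoire.

    ``by_clone`` gives every unique clone weight 1/N; ``by_count``
    weights each gene by the summed clone frequencies, i.e. by reads.
    """
    if segment_class not in ("V", "J"):
        raise ValidationError(f"segment_class must be 'V' or 'J', got {segment_class!r}")
    if weighting not in ("by_clone", "by_count"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    rep.validate()
    col = "v_gene" if segment_class == "V" else "j_gene"
    genes = rep.clones[col]
    if weighting == "by_clone":
        usage = genes.value_counts(normalize=True, sort=False)
    else:
        usage = rep.clones.groupby(col, sort=False)["frequency"].sum()
    return UsageProfile(
        sample_id=rep.metadata.sample_id,
        segment_class=segment_class,
        usage={str(k): float(v) for k, v in usage.items()},
    )
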