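"""Shared fixtures and repertoire-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tcrskin import Repertoire, SampleMetadata, build_repertoire
from tcrskin.simulate import GroupSpec, CohortConfig, simulate_sample


def make_rep(
    clones,
    sample_id="S1",
    patient_id="P1",
    group="normal",
    chain="TRG",
):
    """Build a Repertoire from (nt, aa, v, j, count[, productive]) tuples."""
    rows = []
    for c in clones:
        nt, aa, v, j, count = c[:5]
        productive = c[5] if len(c) > 5 else True
        rows.append(
            {
                "cdr3_nt": nt,
                "cdr3_aa": aa,
                "v_gene": v,
                "d_gene": "",
                "j_gene": j,
                "count": count,
                "productive": productive,
            }
        )
    meta = SampleMetadata(sample_id, patient_id, group, chain)
    return build_repertoire(pd.DataFrame(rows), meta)


def small_config(
    chain="TRG",
    richness=(30, 30, 30),
    depth_mult=20,
    dispersion=0.0,
    freq_shape=5.0,
    **kwargs,
) -> CohortConfig:
    """Tiny three-group config for fast structural tests."""
    names = ("normal", "non_lesional", "lesional")
    n_samples = kwargs.pop("n_samples", (7, 5, 8))
    groups = tuple(
        GroupSpec(
            group=g,
            n_samples=n,
            richness_mean=r,
            richness_dispersion=dispersion,
            depth=depth_mult * r,
        )
        for g, n, r in zip(names, n_samples, richness)
    )
    return CohortConfig(chain=chain, groups=groups, freq_shape=freq_shape, **kwargs)


def random_small_rep(rng: np.random.Generator, sample_id="R", **meta) -> Repertoire:
    """One small simulated repertoire for round-trip/property tests."""
    spec = GroupSpec(
        group=meta.pop("group", "normal"),
        n_samples=1,
        richness_mean=int(rng.integers(5, 40)),
        richness_dispersion=0.3,
    )
    cfg = small_config()
    md = SampleMetadata(
        sample_id,
        meta.pop("patient_id", "P1"),
        spec.group,
        meta.pop("chain", "TRG"),
    )
    return simulate_sample(spec, cfg, rng, metadata=md)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150803)
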