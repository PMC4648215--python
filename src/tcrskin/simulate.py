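"""Synthetic repertoire cohorts with the statistical structure of a
three-group (normal / non-lesional / lesional) skin study.

The generator emulates, at configurable scale:

* heavy-tailed clone-frequency distributions — latent clone weights are
  i.i.d. Pareto with tail exponent ``freq_shape``, normalised to sum
  to 1;
* finite sequencing depth — observed clone counts are a multinomial
  draw of ``depth`` templates from the latent frequencies, so observed
  richness is depth-dependent, and clones with zero draws vanish;
* ~3-fold higher unique-clone richness in lesional skin at comparable
  clonality — per-group richness means follow the study scale, and
  per-group Pareto shapes are calibrated so that expected clonality is
  equal across groups despite the richness gap (see
  :func:`shape_for_clonality`);
* within-patient non-lesional/lesional clone sharing with
  rank-correlated frequencies (Gaussian copula over Pareto marginals);
* cross-patient public clones — a configurable number of amino-acid
  level clones injected into every psoriatic sample, each with an
  independently drawn synonymous nucleotide sequence, so nucleotide
  sharing stays low while amino-acid sharing is high.

Everything is driven by one :class:`numpy.random.Generator`; a whole
cohort is bit-reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from Bio.Data import CodonTable

from .errors import GenerationError, ParameterError
from .io import build_repertoire, write_clone_table, write_manifest
from .types import (
    Chain,
    Repertoire,
    SampleMetadata,
    SourceMaterial,
    TissueGroup,
)

__all__ = [
    "GeneSegmentUsage",
    "GroupSpec",
    "CohortConfig",
    "Cohort",
    "sample_clone_frequencies",
    "shape_for_clonality",
    "generate_rearrangement",
    "simulate_sample",
    "simulate_paired",
    "simulate_cohort",
    "study_config",
    "write_cohort",
    "DEFAULT_SEGMENTS",
]

# ----------------------------------------------------------------------
# genetic code (standard table) for in-frame, stop-free CDR3 generation

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SENSE_CODONS = np.array(sorted(_TABLE.forward_table), dtype="U3")
_CODON_AA = np.array([_TABLE.forward_table[c] for c in _SENSE_CODONS], dtype="U1")
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in zip(_SENSE_CODONS, _CODON_AA):
    _AA_TO_CODONS.setdefault(str(_aa), []).append(str(_codon))

#: CDR3 nucleotide length range (inclusive), multiples of 3
CDR3_NT_RANGE = (27, 54)


@dataclass(frozen=True)
class GeneSegmentUsage:
    """Usage-weighted V and J label alphabets."""

    v: dict[str, float]
    j: dict[str, float]

    def validate(self) -> None:
        for name, alphabet in (("V", self.v), ("J", self.j)):
            if not alphabet:
                raise ParameterError(f"{name} alphabet is empty")
            if any(w <= 0 for w in alphabet.values()):
                raise ParameterError(f"{name} weights must all be positive")


# plausible gene-level alphabets with fixed, arbitrary usage weights
DEFAULT_SEGMENTS: dict[Chain, GeneSegmentUsage] = {
    Chain.TRB: GeneSegmentUsage(
        v={
            "TRBV2": 8, "TRBV4-1": 5, "TRBV5-1": 9, "TRBV6-2": 6,
            "TRBV7-2": 7, "TRBV7-9": 6, "TRBV9": 5, "TRBV12-3": 6,
            "TRBV15": 3, "TRBV19": 6, "TRBV20-1": 10, "TRBV27": 5,
            "TRBV28": 7, "TRBV29-1": 4, "TRBV30": 3,
        },
        j={
            "TRBJ1-1": 8, "TRBJ1-2": 7, "TRBJ1-5": 6, "TRBJ2-1": 10,
            "TRBJ2-2": 5, "TRBJ2-3": 7, "TRBJ2-5": 6, "TRBJ2-7": 9,
        },
    ),
    Chain.TRG: GeneSegmentUsage(
        v={
            "TRGV2": 9, "TRGV3": 7, "TRGV4": 8, "TRGV5": 6,
            "TRGV8": 7, "TRGV9": 12, "TRGV10": 3, "TRGV11": 2,
        },
        j={"TRGJ1": 9, "TRGJ2": 8, "TRGJP": 4, "TRGJP1": 5, "TRGJP2": 5},
    ),
}


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative parameters.

    ``richness_dispersion`` is the coefficient of variation of the
    latent per-sample richness (gamma-distributed around
    ``richness_mean``).  ``freq_shape``, if set, overrides the
    cohort-level Pareto shape for this group.
    """

    group: TissueGroup
    n_samples: int
    richness_mean: int
    richness_dispersion: float = 0.25
    depth: int = 0  # 0 -> 20 x richness_mean
    freq_shape: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "group", TissueGroup(self.group))
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.richness_mean < 2:
            raise ParameterError("richness_mean must be >= 2")
        if self.richness_dispersion < 0:
            raise ParameterError("richness_dispersion must be >= 0")
        if self.depth == 0:
            object.__setattr__(self, "depth", 20 * self.richness_mean)
        if self.depth < self.richness_mean:
            raise ParameterError("depth must be >= richness_mean")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of one synthetic chain cohort."""

    chain: Chain
    groups: tuple[GroupSpec, GroupSpec, GroupSpec]
    freq_shape: float = 2.0
    paired_sharing_rate: float = 0.1
    paired_freq_correlation: float = 0.8
    n_public_clones: int = 0
    public_clone_freq: float = 0.002
    gene_segments: GeneSegmentUsage | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chain", Chain(self.chain))
        seen = {g.group for g in self.groups}
        if seen != set(TissueGroup):
            raise ParameterError("config needs exactly one GroupSpec per tissue group")
        if not 0 <= self.paired_sharing_rate <= 1:
            raise ParameterError("paired_sharing_rate must lie in [0, 1]")
        if not 0 <= self.paired_freq_correlation <= 1:
            raise ParameterError("paired_freq_correlation must lie in [0, 1]")
        if self.n_public_clones < 0:
            raise ParameterError("n_public_clones must be >= 0")
        if not 0 < self.public_clone_freq < 1:
            raise ParameterError("public_clone_freq must lie in (0, 1)")
        if self.gene_segments is None:
            object.__setattr__(self, "gene_segments", DEFAULT_SEGMENTS[self.chain])
        self.gene_segments.validate()

    def spec(self, group: TissueGroup | str) -> GroupSpec:
        group = TissueGroup(group)
        return next(g for g in self.groups if g.group is group)

    def shape_for(self, spec: GroupSpec) -> float:
        return spec.freq_shape if spec.freq_shape is not None else self.freq_shape

    @property
    def n_paired_patients(self) -> int:
        return min(
            self.spec(TissueGroup.NON_LESIONAL).n_samples,
            self.spec(TissueGroup.LESIONAL).n_samples,
        )


@dataclass
class Cohort:
    """In-memory simulated cohort: repertoires plus a manifest frame
    (paths filled in when the cohort is written to disk)."""

    config: CohortConfig
    repertoires: list[Repertoire]
    manifest: pd.DataFrame = field(repr=False)

    def by_group(self, group: TissueGroup | str) -> list[Repertoire]:
        group = TissueGroup(group)
        return [r for r in self.repertoires if r.metadata.group is group]


# ----------------------------------------------------------------------
# latent clone-frequency model


def sample_clone_frequencies(
    n_clones: int, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Normalised i.i.d. Pareto weights with tail exponent ``shape``.

    Small shapes give oligoclonal (heavy-tailed) repertoires; as shape
    grows the weights approach uniformity and clonality tends to 0.
    """
    if shape <= 0:
        raise ParameterError(f"shape must be > 0, got {shape}")
    if n_clones < 1:
        raise ParameterError("n_clones must be >= 1")
    w = rng.pareto(shape, n_clones) + 1.0  # classical Pareto, x_m = 1
    return w / w.sum()


def _entropy_deficit_bits(shape: float) -> float:
    """Asymptotic per-clone entropy deficit D(a) of normalised Pareto
    weights: E[H] ~ log2(n) - D(a), with
    D(a) = [1/(a-1) - ln(a/(a-1))] / ln 2 for a > 1."""
    a = shape
    return (1.0 / (a - 1.0) - np.log(a / (a - 1.0))) / np.log(2.0)


def shape_for_clonality(n_clones: int, target_clonality: float) -> float:
    """Pareto shape whose expected clonality at richness ``n_clones`` is
    ``target_clonality`` (large-n approximation).

    Expected clonality ≈ D(shape) / log2(n); solving for shape lets a
    config hold clonality constant across groups of different richness,
    the structure the study observed.
    """
    if n_clones < 2:
        raise ParameterError("need n_clones >= 2 to calibrate a shape")
    if not 0 < target_clonality < 1:
        raise ParameterError("target_clonality must lie in (0, 1)")
    target_deficit = target_clonality * np.log2(n_clones)

    def f(a: float) -> float:
        return _entropy_deficit_bits(a) - target_deficit

    return float(optimize.brentq(f, 1.0 + 1e-9, 1e6))


# ----------------------------------------------------------------------
# rearrangement generation


def _batch_cdr3(n: int, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """n random in-frame, stop-free CDR3s; returns (nt, aa) lists."""
    lo, hi = CDR3_NT_RANGE
    n_codons = rng.integers(lo // 3, hi // 3 + 1, size=n)
    idx = rng.integers(0, len(_SENSE_CODONS), size=int(n_codons.sum()))
    bounds = np.cumsum(n_codons)[:-1]
    nt = ["".join(part) for part in np.split(_SENSE_CODONS[idx], bounds)]
    aa = ["".join(part) for part in np.split(_CODON_AA[idx], bounds)]
    return nt, aa


def _sample_genes(
    alphabet: dict[str, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    labels = np.array(list(alphabet))
    w = np.array(list(alphabet.values()), dtype=float)
    return rng.choice(labels, size=n, p=w / w.sum())


def _unique_skeletons(
    n: int,
    segments: GeneSegmentUsage,
    rng: np.random.Generator,
    max_rounds: int = 20,
) -> pd.DataFrame:
    """n clone skeletons with unique (nt, V, J) keys."""
    segments.validate()
    nt, aa = _batch_cdr3(n, rng)
    v = _sample_genes(segments.v, n, rng)
    j = _sample_genes(segments.j, n, rng)
    seen: set[tuple] = set()
    keep_nt, keep_aa, keep_v, keep_j = [], [], [], []
    for _ in range(max_rounds):
        for s_nt, s_aa, s_v, s_j in zip(nt, aa, v, j):
            key = (s_nt, s_v, s_j)
            if key in seen:
                continue
            seen.add(key)
            keep_nt.append(s_nt)
            keep_aa.append(s_aa)
            keep_v.append(str(s_v))
            keep_j.append(str(s_j))
        deficit = n - len(keep_nt)
        if deficit == 0:
            return pd.DataFrame(
                {"cdr3_nt": keep_nt, "cdr3_aa": keep_aa, "v_gene": keep_v, "j_gene": keep_j}
            )
        nt, aa = _batch_cdr3(deficit, rng)
        v = _sample_genes(segments.v, deficit, rng)
        j = _sample_genes(segments.j, deficit, rng)
    raise GenerationError(
        f"could not draw {n} unique clone keys in {max_rounds} rounds"
    )


def generate_rearrangement(
    gene_segments: GeneSegmentUsage, rng: np.random.Generator
) -> dict:
    """One random clone skeleton: in-frame CDR3 nt, its translation, and
    weighted V/J labels."""
    row = _unique_skeletons(1, gene_segments, rng).iloc[0]
    return {
        "cdr3_nt": row["cdr3_nt"],
        "cdr3_aa": row["cdr3_aa"],
        "v_gene": row["v_gene"],
        "j_gene": row["j_gene"],
    }


# ----------------------------------------------------------------------
# sample / pair / cohort simulation


def _draw_richness(spec: GroupSpec, rng: np.random.Generator) -> int:
    cv = spec.richness_dispersion
    if cv <= 1e-12:
        return spec.richness_mean
    k = 1.0 / cv**2
    r = rng.gamma(k, spec.richness_mean / k)
    return max(2, int(round(r)))


def _observe(
    skeletons: pd.DataFrame,
    latent_freqs: np.ndarray,
    depth: int,
    metadata: SampleMetadata,
    rng: np.random.Generator,
) -> Repertoire:
    """Multinomial subsampling of latent frequencies at a sequencing depth."""
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    counts = rng.multinomial(depth, latent_freqs)
    keep = counts > 0
    df = skeletons.loc[keep].copy().reset_index(drop=True)
    df["count"] = counts[keep]
    df["d_gene"] = ""
    df["productive"] = True
    return build_repertoire(df, metadata)


def simulate_sample(
    spec: GroupSpec,
    config: CohortConfig,
    rng: np.random.Generator,
    metadata: SampleMetadata | None = None,
) -> Repertoire:
    """One unpaired sample: latent richness -> Pareto frequencies ->
    multinomial counts at the group's depth."""
    if metadata is None:
        metadata = SampleMetadata(
            sample_id=f"{spec.group.value}-sample",
            patient_id="anon",
            group=spec.group,
            chain=config.chain,
        )
    richness = _draw_richness(spec, rng)
    freqs = sample_clone_frequencies(richness, config.shape_for(spec), rng)
    skeletons = _unique_skeletons(richness, config.gene_segments, rng)
    return _observe(skeletons, freqs, spec.depth, metadata, rng)


def _pareto_quantile(u: np.ndarray, shape: float) -> np.ndarray:
    return (1.0 - u) ** (-1.0 / shape)


def simulate_paired(
    patient_id: str,
    nl_spec: GroupSpec,
    ls_spec: GroupSpec,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    sample_ids: tuple[str, str] | None = None,
    return_latent: bool = False,
):
    """A patient's non-lesional / lesional pair.

    A shared clone pool covering ``paired_sharing_rate`` of the lesional
    latent richness receives rank-correlated latent frequencies in the
    two tissues (Gaussian copula with correlation
    ``paired_freq_correlation`` over Pareto marginals); remaining clones
    are private per tissue.  Both samples are then observed by
    independent multinomial subsampling.
    """
    nl_rich = _draw_richness(nl_spec, rng)
    ls_rich = _draw_richness(ls_spec, rng)
    n_shared = int(round(config.paired_sharing_rate * ls_rich))
    if n_shared > min(nl_rich, ls_rich):
        raise ParameterError(
            f"sharing rate {config.paired_sharing_rate} demands {n_shared} shared "
            f"clones but the smaller repertoire holds only {min(nl_rich, ls_rich)}"
        )
    rho = config.paired_freq_correlation
    z1 = rng.standard_normal(n_shared)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_shared)
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    a_nl = config.shape_for(nl_spec)
    a_ls = config.shape_for(ls_spec)
    w_nl_shared = _pareto_quantile(u1, a_nl)
    w_ls_shared = _pareto_quantile(u2, a_ls)
    w_nl_priv = rng.pareto(a_nl, nl_rich - n_shared) + 1.0
    w_ls_priv = rng.pareto(a_ls, ls_rich - n_shared) + 1.0
    w_nl = np.concatenate([w_nl_shared, w_nl_priv])
    w_ls = np.concatenate([w_ls_shared, w_ls_priv])
    f_nl = w_nl / w_nl.sum()
    f_ls = w_ls / w_ls.sum()

    pool = _unique_skeletons(
        nl_rich + ls_rich - n_shared, config.gene_segments, rng
    )
    shared_skel = pool.iloc[:n_shared]
    nl_skel = pd.concat(
        [shared_skel, pool.iloc[n_shared:nl_rich]], ignore_index=True
    )
    ls_skel = pd.concat(
        [shared_skel, pool.iloc[nl_rich : nl_rich + ls_rich - n_shared]],
        ignore_index=True,
    )
    nl_id, ls_id = sample_ids or (f"{patient_id}-NL", f"{patient_id}-LS")
    source = (
        SourceMaterial.gDNA if config.chain is Chain.TRB else SourceMaterial.cDNA
    )
    nl_rep = _observe(
        nl_skel,
        f_nl,
        nl_spec.depth,
        SampleMetadata(nl_id, patient_id, TissueGroup.NON_LESIONAL, config.chain, source),
        rng,
    )
    ls_rep = _observe(
        ls_skel,
        f_ls,
        ls_spec.depth,
        SampleMetadata(ls_id, patient_id, TissueGroup.LESIONAL, config.chain, source),
        rng,
    )
    if return_latent:
        latent = {
            "shared_freq_nl": f_nl[:n_shared],
            "shared_freq_ls": f_ls[:n_shared],
            "n_shared": n_shared,
            "nl_richness": nl_rich,
            "ls_richness": ls_rich,
        }
        return nl_rep, ls_rep, latent
    return nl_rep, ls_rep


def _synonymous_nt(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _AA_TO_CODONS[res][rng.integers(0, len(_AA_TO_CODONS[res]))] for res in aa
    )


def _inject_public(
    rep: Repertoire,
    public_aa: list[str],
    config: CohortConfig,
    rng: np.random.Generator,
) -> Repertoire:
    """Append the public amino-acid clones to one psoriatic sample, each
    with a freshly drawn synonymous nucleotide sequence, at low count,
    then re-collapse and renormalise."""
    total = rep.total_count
    count = max(1, int(round(config.public_clone_freq * total)))
    rows = []
    for aa in public_aa:
        rows.append(
            {
                "cdr3_nt": _synonymous_nt(aa, rng),
                "cdr3_aa": aa,
                "v_gene": str(_sample_genes(config.gene_segments.v, 1, rng)[0]),
                "d_gene": "",
                "j_gene": str(_sample_genes(config.gene_segments.j, 1, rng)[0]),
                "count": count,
                "productive": True,
            }
        )
    df = pd.concat(
        [rep.clones.drop(columns="frequency"), pd.DataFrame(rows)],
        ignore_index=True,
    )
    return build_repertoire(df, rep.metadata)


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Full three-group cohort for one chain.

    Normal samples come from their own patients; the first
    ``min(n_NL, n_LS)`` psoriatic patients contribute a paired NL/LS
    sample each, remaining lesional samples are unpaired patients.
    Public amino-acid clones are injected into every psoriatic sample
    and no normal sample.
    """
    rng = np.random.default_rng(config.seed)
    source = (
        SourceMaterial.gDNA if config.chain is Chain.TRB else SourceMaterial.cDNA
    )
    chain = config.chain.value
    normal_spec = config.spec(TissueGroup.NORMAL)
    nl_spec = config.spec(TissueGroup.NON_LESIONAL)
    ls_spec = config.spec(TissueGroup.LESIONAL)

    reps: list[Repertoire] = []
    for i in range(normal_spec.n_samples):
        pid = f"NRM{i + 1:02d}"
        meta = SampleMetadata(
            f"{pid}-N-{chain}", pid, TissueGroup.NORMAL, config.chain, source
        )
        reps.append(simulate_sample(normal_spec, config, rng, metadata=meta))

    n_paired = config.n_paired_patients
    for i in range(n_paired):
        pid = f"PSO{i + 1:02d}"
        nl_rep, ls_rep = simulate_paired(
            pid,
            nl_spec,
            ls_spec,
            config,
            rng,
            sample_ids=(f"{pid}-NL-{chain}", f"{pid}-LS-{chain}"),
        )
        reps.extend([nl_rep, ls_rep])
    for i in range(n_paired, ls_spec.n_samples):
        pid = f"PSO{i + 1:02d}"
        meta = SampleMetadata(
            f"{pid}-LS-{chain}", pid, TissueGroup.LESIONAL, config.chain, source
        )
        reps.append(simulate_sample(ls_spec, config, rng, metadata=meta))
    for i in range(n_paired, nl_spec.n_samples):
        # unpaired extra non-lesional samples, if the config asks for them
        pid = f"PSO{ls_spec.n_samples + (i - n_paired) + 1:02d}"
        meta = SampleMetadata(
            f"{pid}-NL-{chain}", pid, TissueGroup.NON_LESIONAL, config.chain, source
        )
        reps.append(simulate_sample(nl_spec, config, rng, metadata=meta))

    if config.n_public_clones > 0:
        _, public_aa = _batch_cdr3(config.n_public_clones, rng)
        reps = [
            rep
            if rep.metadata.group is TissueGroup.NORMAL
            else _inject_public(rep, public_aa, config, rng)
            for rep in reps
        ]

    manifest = pd.DataFrame(
        {
            "sample_id": [r.metadata.sample_id for r in reps],
            "patient_id": [r.metadata.patient_id for r in reps],
            "group": [r.metadata.group.value for r in reps],
            "chain": [r.metadata.chain.value for r in reps],
            "source_material": [r.metadata.source_material.value for r in reps],
            "path": [f"{r.metadata.sample_id}.tsv" for r in reps],
        }
    )
    return Cohort(config=config, repertoires=reps, manifest=manifest)


def study_config(
    chain: Chain | str = Chain.TRG,
    seed: int = 0,
    *,
    target_clonality: float = 0.08,
    scale: float = 1.0,
) -> CohortConfig:
    """Default cohort config mirroring the study design.

    7 normal, 5 non-lesional and 8 lesional samples (5 paired
    patients); group richness means follow the reported per-chain
    averages (β: 2700 / 3200 / 10900; γ: 397 / 558 / 1570 unique
    clones); sequencing depth is 20x the richness mean; per-group
    Pareto shapes are calibrated to a common expected clonality, and
    three public amino-acid clones are injected into psoriatic γ-chain
    samples (none for β).  ``scale`` shrinks richness for fast smoke
    tests without touching the group ratios.
    """
    chain = Chain(chain)
    richness = {
        Chain.TRB: {"normal": 2700, "non_lesional": 3200, "lesional": 10900},
        Chain.TRG: {"normal": 397, "non_lesional": 558, "lesional": 1570},
    }[chain]
    n_samples = {"normal": 7, "non_lesional": 5, "lesional": 8}
    groups = tuple(
        GroupSpec(
            group=g,
            n_samples=n_samples[g],
            richness_mean=max(2, int(round(scale * richness[g]))),
            richness_dispersion=0.25,
            freq_shape=shape_for_clonality(
                max(2, int(round(scale * richness[g]))), target_clonality
            ),
        )
        for g in ("normal", "non_lesional", "lesional")
    )
    return CohortConfig(
        chain=chain,
        groups=groups,
        paired_sharing_rate=0.1,
        paired_freq_correlation=0.8,
        n_public_clones=3 if chain is Chain.TRG else 0,
        seed=seed,
    )


def write_cohort(
    cohort: Cohort, outdir, dialect: str = "immunoseq"
) -> "pd.DataFrame":
    """Write per-sample clone tables and the manifest; returns the
    manifest with relative paths as written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in cohort.repertoires:
        write_clone_table(rep, outdir / f"{rep.metadata.sample_id}.tsv", dialect)
    write_manifest(cohort.manifest, outdir / "manifest.tsv")
    return cohort.manifest
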