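"""Reading, validating, normalising and writing clone tables.

Two TSV dialects are supported:

``immunoseq``
    The vendor-style export with columns ``nucleotide, aminoAcid, count,
    frequencyCount, vGeneName, dGeneName, jGeneName, sequenceStatus``.
    ``sequenceStatus`` is "In" for productive rearrangements, "Out" /
    "Stop" otherwise.  If an optional ``templates`` column is present
    with positive values it is preferred over ``count`` (template counts
    are PCR-bias-corrected molecule estimates).
``airr``
    AIRR Rearrangement schema column names: ``junction`` (or
    ``sequence``), ``junction_aa, duplicate_count, v_call, d_call,
    j_call, productive`` with "T"/"F" productivity flags.

On read, rows are collapsed by the ``nt_vj`` identity key (counts
summed) and frequencies are recomputed as count / total count, so the
frequency column of the input file is informational only.  Gene calls
are normalised to gene level: allele suffixes (``*01``) are stripped and
the first gene of a comma-separated ambiguous call is kept.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .errors import DialectError, ValidationError
from .types import (
    CLONE_COLUMNS,
    Chain,
    CloneRecord,
    KeyMode,
    Repertoire,
    SampleMetadata,
    SourceMaterial,
    TissueGroup,
)

__all__ = [
    "read_clone_table",
    "write_clone_table",
    "identity_key",
    "filter_productive",
    "build_repertoire",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "MANIFEST_COLUMNS",
]

_IMMUNOSEQ_REQUIRED = [
    "nucleotide",
    "aminoAcid",
    "count",
    "frequencyCount",
    "vGeneName",
    "dGeneName",
    "jGeneName",
    "sequenceStatus",
]
_AIRR_REQUIRED = [
    "junction_aa",
    "duplicate_count",
    "v_call",
    "d_call",
    "j_call",
    "productive",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "patient_id",
    "group",
    "chain",
    "source_material",
    "path",
]

_AIRR_TRUE = {"t", "true", "1", "yes"}
_AIRR_FALSE = {"f", "false", "0", "no", ""}


def _clean_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def _clean_gene(value) -> str:
    """Normalise a gene call to gene level.

    Ambiguous multi-gene calls keep the first listed gene; allele
    suffixes after '*' are stripped.
    """
    g = _clean_str(value)
    if not g:
        return ""
    g = g.split(",")[0].strip()
    return g.split("*")[0].strip()


def identity_key(clone: CloneRecord, mode: KeyMode | str = KeyMode.NT_VJ) -> tuple:
    """Opaque comparable identity key for one clone.

    ``nt_vj`` keys on (CDR3 nucleotide, V gene, J gene); the D call is
    deliberately excluded (often unresolved, and absent for the
    γ-chain).  ``aa_only`` keys on the CDR3 amino-acid sequence alone.
    """
    mode = KeyMode(mode)
    if mode is KeyMode.NT_VJ:
        return ("nt", clone.cdr3_nt, clone.v_gene, clone.j_gene)
    if not clone.cdr3_aa:
        raise ValidationError(
            "cannot key a clone with empty CDR3 amino-acid sequence by aa_only"
        )
    return ("aa", clone.cdr3_aa)


def build_repertoire(df: pd.DataFrame, metadata: SampleMetadata) -> Repertoire:
    """Collapse a raw clone DataFrame into a valid :class:`Repertoire`.

    Rows sharing an ``nt_vj`` key are merged with counts summed;
    frequencies are recomputed as count/total; clones are ordered by
    descending count with input order preserved among ties.
    """
    if len(df) == 0:
        raise ValidationError(
            f"sample {metadata.sample_id}: a repertoire must have at least one clone"
        )
    bad = df.index[df["count"] < 1]
    if len(bad) > 0:
        raise ValidationError(
            f"sample {metadata.sample_id}: non-positive count in row "
            f"{int(bad[0]) + 1}"
        )
    key = list(zip(df["cdr3_nt"], df["v_gene"], df["j_gene"]))
    df = df.assign(_key=pd.Series(key, index=df.index))
    collapsed = (
        df.groupby("_key", sort=False, as_index=False)
        .agg(
            cdr3_nt=("cdr3_nt", "first"),
            cdr3_aa=("cdr3_aa", "first"),
            v_gene=("v_gene", "first"),
            d_gene=("d_gene", "first"),
            j_gene=("j_gene", "first"),
            count=("count", "sum"),
            productive=("productive", "first"),
        )
        .drop(columns="_key")
    )
    collapsed = collapsed.sort_values(
        "count", ascending=False, kind="stable", ignore_index=True
    )
    total = int(collapsed["count"].sum())
    collapsed["frequency"] = collapsed["count"] / total
    collapsed["count"] = collapsed["count"].astype(int)
    collapsed["productive"] = collapsed["productive"].astype(bool)
    rep = Repertoire(metadata, collapsed[CLONE_COLUMNS])
    rep.validate()
    return rep


def _parse_counts(series: pd.Series, sample_id: str) -> pd.Series:
    counts = pd.to_numeric(series, errors="coerce")
    bad = counts.index[counts.isna() | (counts < 1)]
    if len(bad) > 0:
        raise ValidationError(
            f"sample {sample_id}: non-positive or unparseable count in data row "
            f"{int(bad[0]) + 1}"
        )
    return counts.astype(int)


def read_clone_table(
    path: str | os.PathLike,
    dialect: str,
    metadata: SampleMetadata,
) -> Repertoire:
    """Read one sample's clone table and return a collapsed Repertoire."""
    path = Path(path)
    if dialect not in ("immunoseq", "airr"):
        raise DialectError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = _IMMUNOSEQ_REQUIRED if dialect == "immunoseq" else _AIRR_REQUIRED
    for col in required:
        if col not in raw.columns:
            raise DialectError(
                f"{path.name}: {dialect} dialect requires column {col!r}"
            )
    if dialect == "airr" and not ({"junction", "sequence"} & set(raw.columns)):
        raise DialectError(
            f"{path.name}: airr dialect requires a 'junction' or 'sequence' column"
        )
    if len(raw) == 0:
        raise ValidationError(f"{path.name}: empty clone table")

    if dialect == "immunoseq":
        count_col = "count"
        if "templates" in raw.columns:
            templates = pd.to_numeric(raw["templates"], errors="coerce")
            if templates.notna().all() and (templates >= 1).all():
                count_col = "templates"
        df = pd.DataFrame(
            {
                "cdr3_nt": raw["nucleotide"].map(_clean_str),
                "cdr3_aa": raw["aminoAcid"].map(_clean_str),
                "v_gene": raw["vGeneName"].map(_clean_gene),
                "d_gene": raw["dGeneName"].map(_clean_gene),
                "j_gene": raw["jGeneName"].map(_clean_gene),
                "count": _parse_counts(raw[count_col], metadata.sample_id),
                "productive": raw["sequenceStatus"]
                .map(_clean_str)
                .str.lower()
                .eq("in"),
            }
        )
    else:
        nt_col = "junction" if "junction" in raw.columns else "sequence"

        def _parse_bool(value) -> bool:
            v = _clean_str(value).lower()
            if v in _AIRR_TRUE:
                return True
            if v in _AIRR_FALSE:
                return False
            raise ValidationError(
                f"{path.name}: unrecognised productive flag {value!r}"
            )

        df = pd.DataFrame(
            {
                "cdr3_nt": raw[nt_col].map(_clean_str),
                "cdr3_aa": raw["junction_aa"].map(_clean_str),
                "v_gene": raw["v_call"].map(_clean_gene),
                "d_gene": raw["d_call"].map(_clean_gene),
                "j_gene": raw["j_call"].map(_clean_gene),
                "count": _parse_counts(raw["duplicate_count"], metadata.sample_id),
                "productive": raw["productive"].map(_parse_bool),
            }
        )
    if (df["cdr3_nt"] == "").any():
        raise ValidationError(f"{path.name}: row with empty CDR3 nucleotide sequence")
    return build_repertoire(df, metadata)


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep only productive clones, renormalising frequencies.

    The input repertoire is not modified.  Raises if nothing survives:
    an empty repertoire is not a valid analysis unit.
    """
    kept = rep.clones[rep.clones["productive"]].copy().reset_index(drop=True)
    if len(kept) == 0:
        raise ValidationError(
            f"sample {rep.metadata.sample_id}: no productive clones remain"
        )
    kept["frequency"] = kept["count"] / int(kept["count"].sum())
    out = Repertoire(rep.metadata, kept[CLONE_COLUMNS])
    out.validate()
    return out


def write_clone_table(
    rep: Repertoire, path: str | os.PathLike, dialect: str
) -> None:
    """Write a repertoire as TSV; round-trips through read_clone_table."""
    if dialect not in ("immunoseq", "airr"):
        raise DialectError(f"unknown dialect {dialect!r}")
    rep.validate()
    df = rep.clones
    for col in ("cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene"):
        joined = "".join(df[col].astype(str))
        if "\t" in joined or "\n" in joined:
            raise ValidationError(
                f"field {col!r} contains a tab or newline; cannot write TSV"
            )
    if dialect == "immunoseq":
        out = pd.DataFrame(
            {
                "nucleotide": df["cdr3_nt"],
                "aminoAcid": df["cdr3_aa"],
                "count": df["count"],
                # vendor convention: percent of total
                "frequencyCount": df["frequency"] * 100.0,
                "vGeneName": df["v_gene"],
                "dGeneName": df["d_gene"],
                "jGeneName": df["j_gene"],
                "sequenceStatus": df["productive"].map({True: "In", False: "Out"}),
            }
        )
    else:
        out = pd.DataFrame(
            {
                "junction": df["cdr3_nt"],
                "junction_aa": df["cdr3_aa"],
                "duplicate_count": df["count"],
                "v_call": df["v_gene"],
                "d_call": df["d_gene"],
                "j_call": df["j_gene"],
                "productive": df["productive"].map({True: "T", False: "F"}),
            }
        )
    out.to_csv(path, sep="\t", index=False)


# -- cohort manifest -----------------------------------------------------


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    dup = manifest["sample_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate sample_id in manifest: {manifest['sample_id'][dup].iloc[0]}"
        )
    # the same patient cannot be both a healthy control and a case
    normal = set(manifest.loc[manifest["group"] == "normal", "patient_id"])
    pso = set(manifest.loc[manifest["group"] != "normal", "patient_id"])
    overlap = normal & pso
    if overlap:
        raise ValidationError(
            f"patient(s) {sorted(overlap)} appear in both normal and psoriatic groups"
        )
    return manifest


def load_cohort(
    manifest_path: str | os.PathLike, dialect: str
) -> list[Repertoire]:
    """Read every sample listed in a manifest, resolving relative paths
    against the manifest's directory."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    reps = []
    for row in manifest.itertuples(index=False):
        meta = SampleMetadata(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            group=TissueGroup(row.group),
            chain=Chain(row.chain),
            source_material=SourceMaterial(row.source_material)
            if _clean_str(row.source_material)
            else None,
        )
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        reps.append(read_clone_table(p, dialect, meta))
    return reps
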