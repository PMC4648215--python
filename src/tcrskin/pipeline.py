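"""End-to-end analysis orchestration.

``run_pipeline`` executes read → productive filter → diversity →
overlap → paired comparison → public clones → group inference for every
chain present in a cohort manifest, never mixing chains within a
statistic, and writes a machine-readable JSON report plus per-stage
TSV tables.  The run is deterministic: identical inputs and config give
a byte-identical report payload.

On any stage failure the pipeline halts with stage and sample context
and removes partially written outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import diversity_table
from .errors import PipelineError, TcrskinError
from .inference import compare_metric_across_groups
from .io import filter_productive, load_cohort, read_manifest
from .overlap import (
    common_clones,
    overlap_table,
    paired_comparison,
    pool_overlaps,
)
from .types import Chain, KeyMode, Repertoire, TissueGroup

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    manifest: str
    out_dir: str
    dialect: str = "immunoseq"
    paired_key_mode: KeyMode = KeyMode.NT_VJ
    public_key_mode: KeyMode = KeyMode.AA_ONLY
    overlap_norm: str = "jaccard"
    productive_only: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise PipelineError("significance threshold must lie in (0, 1)")
        object.__setattr__(self, "paired_key_mode", KeyMode(self.paired_key_mode))
        object.__setattr__(self, "public_key_mode", KeyMode(self.public_key_mode))


@dataclass
class AnalysisReport:
    config: RunConfig
    payload: dict = field(repr=False)

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with stage context."""

    class _Ctx:
        def __init__(self, ctx=""):
            self.ctx = ctx

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {name!r}{(' [' + self.ctx + ']') if self.ctx else ''}: {exc}"
                ) from exc
            return False

    return _Ctx()


def _analyze_chain(
    reps: list[Repertoire], config: RunConfig, out: Path, written: list[Path]
) -> dict:
    chain = reps[0].metadata.chain.value

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{chain}_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    with _stage("diversity"):
        div = diversity_table(reps, productive_only=config.productive_only)
        emit("diversity", div)

    with _stage("overlap"):
        records = pool_overlaps(
            reps, key_mode=config.public_key_mode, norm=config.overlap_norm
        )
        ov = overlap_table(records)
        emit("overlap", ov)
        pooled = ov[~ov["excluded"]]
        pooled_summary = {
            g: {
                "n_pairs": int((pooled["comparison_group"] == g).sum()),
                "mean_score": float(
                    pooled.loc[pooled["comparison_group"] == g, "score"].mean()
                ),
            }
            for g in sorted(pooled["comparison_group"].unique())
        }

    with _stage("paired"):
        analysis_reps = (
            [filter_productive(r) for r in reps] if config.productive_only else reps
        )
        by_patient: dict[str, dict[str, Repertoire]] = {}
        for rep in analysis_reps:
            if rep.metadata.group is not TissueGroup.NORMAL:
                by_patient.setdefault(rep.metadata.patient_id, {})[
                    rep.metadata.group.value
                ] = rep
        paired = []
        for pid in sorted(by_patient):
            pair = by_patient[pid]
            if "non_lesional" in pair and "lesional" in pair:
                pc = paired_comparison(
                    pair["non_lesional"],
                    pair["lesional"],
                    key_mode=config.paired_key_mode,
                )
                paired.append(pc)
                shared = pc.shared.copy()
                shared["set"] = "shared"
                nl = pc.unique_nl.copy()
                nl["set"] = "unique_nl"
                ls = pc.unique_ls.copy()
                ls["set"] = "unique_ls"
                emit(
                    f"paired_{pid}",
                    pd.concat([shared, nl, ls], ignore_index=True).assign(
                        key=lambda d: d["key"].astype(str)
                    ),
                )
        paired_summary = {p.patient_id: p.counts for p in paired}

    with _stage("public_clones"):
        lesional = [
            r
            for r in analysis_reps
            if r.metadata.group is TissueGroup.LESIONAL
        ]
        psoriatic = [
            r
            for r in analysis_reps
            if r.metadata.group is not TissueGroup.NORMAL
        ]
        normal = [
            r for r in analysis_reps if r.metadata.group is TissueGroup.NORMAL
        ]
        public = {}
        for scope, scoped in (
            ("lesional", lesional),
            ("psoriatic", psoriatic),
            ("normal", normal),
        ):
            if not scoped:
                continue
            report = common_clones(scoped, key_mode=config.public_key_mode)
            public[scope] = {
                "n_samples": len(scoped),
                "n_common_clones": report.n_clones,
                "clones": [str(k) for k in report.clones["key"].tolist()],
            }
            df = report.clones.copy()
            df["key"] = df["key"].astype(str)
            emit(f"public_{scope}", df)

    with _stage("inference"):
        results = []
        for metric in ("unique_count", "clonality"):
            results.extend(
                compare_metric_across_groups(
                    diversity=div, metric=metric, alpha=config.alpha
                )
            )
        results.extend(
            compare_metric_across_groups(
                overlaps=ov, metric="overlap_score", alpha=config.alpha
            )
        )
        inference = [r.as_dict() for r in results]
        emit(
            "inference",
            pd.DataFrame(
                [
                    {
                        "metric": r["metric"],
                        "test": r["test"],
                        "groups": "|".join(r["groups"]),
                        "statistic": r["statistic"],
                        "df": "|".join(str(d) for d in r["df"]),
                        "p_value": r["p_value"],
                        "significant": r["significant"],
                        "degenerate": r["degenerate"],
                    }
                    for r in inference
                ]
            ),
        )

    return {
        "n_samples": len(reps),
        "diversity": div.to_dict("records"),
        "pooled_overlap": pooled_summary,
        "n_overlap_records": len(ov),
        "n_excluded_overlap_records": int(ov["excluded"].sum()),
        "paired": paired_summary,
        "public_clones": public,
        "inference": inference,
        "n_tests": len(inference),
    }


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run the full analysis described by ``config``; returns the report
    and writes ``report.json`` plus stage TSVs to the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with _stage("read"):
            manifest_path = Path(config.manifest)
            manifest = read_manifest(manifest_path)
            for p in manifest["path"]:
                f = Path(p)
                if not f.is_absolute():
                    f = manifest_path.parent / f
                if not f.exists():
                    raise PipelineError(
                        f"stage 'read': clone table not found: {f}"
                    )
            cohort = load_cohort(manifest_path, config.dialect)

        chains: dict[str, list[Repertoire]] = {}
        for rep in cohort:
            chains.setdefault(rep.metadata.chain.value, []).append(rep)

        payload = {
            "chains": {
                chain: _analyze_chain(reps, config, out, written)
                for chain, reps in sorted(chains.items())
            },
            "provenance": {
                "tcrskin_version": __version__,
                "config": {
                    "manifest": str(config.manifest),
                    "dialect": config.dialect,
                    "paired_key_mode": config.paired_key_mode.value,
                    "public_key_mode": config.public_key_mode.value,
                    "overlap_norm": config.overlap_norm,
                    "productive_only": config.productive_only,
                    "alpha": config.alpha,
                    "seed": config.seed,
                },
                "input_checksums": {
                    row.sample_id: _sha256(
                        (manifest_path.parent / row.path)
                        if not Path(row.path).is_absolute()
                        else Path(row.path)
                    )
                    for row in manifest.itertuples(index=False)
                },
            },
        }
        report = AnalysisReport(config=config, payload=payload)
        report_path = out / "report.json"
        report_path.write_text(report.to_json())
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def halt_message(err: TcrskinError) -> str:
    return f"pipeline halted: {err}"
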