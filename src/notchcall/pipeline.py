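"""End-to-end orchestration with config files, seeding and provenance.

Both pipelines are pure functions of their declared inputs: every output
table carries a provenance header comment with the config hash and seed, so
a rerun with identical config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import efficacy as eff_mod
from .caller import CallerConfig, call_activation, score_cohort, signature_cluster
from .io_formats import (
    ExpressionMatrix,
    GrowthTable,
    read_expression_matrix,
    read_growth_table,
    write_results,
)
from .signature import default_signature, load_signature_gmt

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_caller_pipeline", "run_efficacy_pipeline", "default_config"]


@dataclass
class RunConfig:
    """Pipeline configuration; every tunable threshold is surfaced here."""

    expression_path: str | None = None
    signature_gmt: str | None = None  # None -> packaged default signature
    growth_path: str | None = None
    output_dir: str = "notchcall_out"
    seed: int = 0
    # caller
    tau: float = 0.25
    normalize_scores: bool = True
    ktsp_threshold: float = 0.5
    ssgsea_threshold: float | None = None
    cluster_k: int = 2
    # DE thresholds
    mean_min: float = 50.0
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    pseudocount: float = 0.5
    # efficacy
    baseline_day: int | None = None
    final_day: int | None = None
    tgi_summary: str = "mean"
    control_group: str | None = None

    def config_hash(self) -> str:
        # output_dir is excluded: where results land does not change them
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def default_config() -> RunConfig:
    return RunConfig()


def _write_with_provenance(
    path: Path, table: pd.DataFrame, config: RunConfig, stage: str
) -> None:
    header = f"# notchcall stage={stage} config_hash={config.config_hash()} seed={config.seed}\n"
    body_path = path
    with open(body_path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    logger.info("stage %s: wrote %d rows to %s", stage, len(table), path)


def run_caller_pipeline(
    config: RunConfig, matrix: ExpressionMatrix | None = None
) -> dict:
    """normalize -> score -> call -> cluster.

    ``matrix`` may be passed directly (raw or normalized); otherwise it is
    read from ``config.expression_path``.  Outputs are written under
    ``config.output_dir`` and also returned in-memory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if matrix is None:
            if config.expression_path is None:
                raise ValueError("no expression matrix given")
            matrix = read_expression_matrix(config.expression_path, kind="raw")
        signature = (
            load_signature_gmt(config.signature_gmt)
            if config.signature_gmt
            else default_signature()
        )
        stage = "normalize"
        if matrix.kind.value == "raw":
            factors = de_mod.size_factors(matrix)
            norm = de_mod.normalize_counts(matrix, factors)
        else:
            norm = matrix
        stage = "score"
        caller_cfg = CallerConfig(
            tau=config.tau,
            normalize_scores=config.normalize_scores,
            ktsp_threshold=config.ktsp_threshold,
            ssgsea_threshold=config.ssgsea_threshold,
        )
        scores = score_cohort(norm, signature, caller_cfg)
        stage = "call"
        calls = call_activation(scores, caller_cfg)
        stage = "cluster"
        linkage, labels = signature_cluster(norm, signature, k=config.cluster_k)
        cluster_table = labels.rename("cluster").rename_axis("sample_id").reset_index()

        norm_table = norm.to_frame().reset_index(names="gene_id")
        _write_with_provenance(outdir / "normalized_matrix.tsv", norm_table, config, "normalize")
        _write_with_provenance(outdir / "activation_calls.tsv", calls, config, "call")
        _write_with_provenance(outdir / "signature_clusters.tsv", cluster_table, config, "cluster")
        sig_sub = norm.subset_genes(signature.up_genes + signature.down_genes)
        _write_with_provenance(
            outdir / "signature_matrix.tsv",
            sig_sub.to_frame().reset_index(names="gene_id"),
            config,
            "cluster",
        )
        return {
            "normalized": norm,
            "scores": scores,
            "calls": calls,
            "linkage": linkage,
            "cluster_labels": labels,
        }
    except Exception as exc:
        raise RuntimeError(f"caller pipeline failed at stage {stage!r}: {exc}") from exc


def run_efficacy_pipeline(
    config: RunConfig, growth: GrowthTable | None = None
) -> dict:
    """volumes -> %TGI (each treated group vs control) -> slopes -> ANOVA/Tukey."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if growth is None:
            if config.growth_path is None:
                raise ValueError("no growth table given")
            growth = read_growth_table(config.growth_path)
        stage = "volumes"
        volumes = eff_mod.ensure_volumes(growth)
        stage = "tgi"
        groups = growth.groups
        control = config.control_group or (
            "vehicle" if "vehicle" in groups else groups[0]
        )
        tgi_rows = []
        for g in groups:
            if g == control:
                continue
            res = eff_mod.percent_tgi(
                growth, g, control,
                baseline_day=config.baseline_day,
                final_day=config.final_day,
                summary=config.tgi_summary,
            )
            tgi_rows.append(vars(res))
        tgi_table = pd.DataFrame(tgi_rows)
        stage = "slopes"
        slopes = eff_mod.growth_slopes(growth)
        stage = "anova"
        comparison = eff_mod.anova_tukey(slopes)

        _write_with_provenance(outdir / "volumes.tsv", volumes, config, "volumes")
        _write_with_provenance(outdir / "tgi.tsv", tgi_table, config, "tgi")
        _write_with_provenance(outdir / "growth_slopes.tsv", slopes, config, "slopes")
        pw = comparison["pairwise"].copy()
        pw.insert(0, "anova_F", comparison["anova_F"])
        pw.insert(1, "anova_p", comparison["anova_p"])
        _write_with_provenance(outdir / "group_comparisons.tsv", pw, config, "anova")
        return {
            "volumes": volumes,
            "tgi": tgi_table,
            "slopes": slopes,
            "comparison": comparison,
        }
    except Exception as exc:
        raise RuntimeError(f"efficacy pipeline failed at stage {stage!r}: {exc}") from exc
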