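"""Whole-pipeline orchestration, run logging, and wide-matrix export.

The run configuration groups every tunable of the analysis; running it writes
the expression table, the gene-action table, influence tallies (overall and
per hybrid / tissue / category), the trait summary when traits are supplied,
and a run log echoing the configuration and per-stage record counts so that
silently omitted rows are visible. Identical inputs and configuration produce
byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .errors import ValidationError
from .io_tables import (read_annotation, read_ct_table, read_pedigree,
                        read_trait_table, records_to_frame, write_results)
from .expression import RelativeExpression, expression_table
from .gene_action import (DEFAULT_ADDITIVE_HALFWIDTH, DEFAULT_DOMINANCE_BOUND,
                          DEFAULT_EPSILON, GeneActionResult, InfluenceTally,
                          Scale, gene_action_table, nonadditive_fraction,
                          tally_influence)
from .traits import trait_summary

logger = logging.getLogger("trioqpcr")

__all__ = ["RunConfig", "run_pipeline", "export_matrix"]


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one analysis run."""

    ct_path: Path
    pedigree_path: Path
    output_dir: Path
    annotation_path: Path | None = None
    traits_path: Path | None = None
    reference_gene_id: str = "18S"
    scale: Scale | str = Scale.LINEAR
    additive_halfwidth: float = DEFAULT_ADDITIVE_HALFWIDTH
    dominance_bound: float = DEFAULT_DOMINANCE_BOUND
    epsilon: float = DEFAULT_EPSILON
    trait_comparison: str = "stress_vs_control"
    log_level: str = "INFO"

    def __post_init__(self):
        for f in ("ct_path", "pedigree_path", "output_dir",
                  "annotation_path", "traits_path"):
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, Path(v))
        self.scale = Scale(str(self.scale).strip().lower()) if not isinstance(
            self.scale, Scale) else self.scale
        problems = []
        if not self.additive_halfwidth < self.dominance_bound:
            problems.append(
                f"additive_halfwidth ({self.additive_halfwidth}) must be < "
                f"dominance_bound ({self.dominance_bound})")
        if self.additive_halfwidth <= 0:
            problems.append("additive_halfwidth must be > 0")
        if self.epsilon <= 0:
            problems.append(f"epsilon must be > 0, got {self.epsilon}")
        if problems:
            raise ValidationError("invalid RunConfig", problems)

    def echo(self) -> str:
        lines = [f"trioqpcr {__version__}"]
        for f in fields(self):
            v = getattr(self, f.name)
            v = v.value if isinstance(v, Scale) else v
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a name -> path map of outputs."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [config.echo(), ""]

    ct = read_ct_table(config.ct_path, config.reference_gene_id)
    log_lines.append(f"ct_records = {len(ct)}")
    pedigree = read_pedigree(config.pedigree_path)
    log_lines.append(f"pedigree_entries = {len(pedigree)}")
    annotation = (read_annotation(config.annotation_path)
                  if config.annotation_path else None)
    if annotation is not None:
        log_lines.append(f"gene_annotations = {len(annotation)}")

    expr = expression_table(ct, config.reference_gene_id)
    log_lines.append(f"expression_rows = {len(expr)}")
    results = gene_action_table(
        expr, pedigree, scale=config.scale, annotation=annotation,
        additive_halfwidth=config.additive_halfwidth,
        dominance_bound=config.dominance_bound, epsilon=config.epsilon)
    log_lines.append(f"gene_action_rows = {len(results)}")

    tallies: list[InfluenceTally] = tally_influence(results)
    for by in ("hybrid_id", "tissue", "category"):
        if by == "category" and annotation is None:
            continue
        tallies.extend(tally_influence(results, by=by))
    frac = nonadditive_fraction(results)
    log_lines.append(f"nonadditive_fraction = {frac!r}")

    outputs: dict[str, Path] = {}
    outputs["expression"] = out / "expression.tsv"
    write_results(expr, outputs["expression"], record_type=RelativeExpression)
    outputs["gene_action"] = out / "gene_action.tsv"
    write_results(results, outputs["gene_action"], record_type=GeneActionResult)
    outputs["tallies"] = out / "tallies.tsv"
    write_results(tallies, outputs["tallies"], record_type=InfluenceTally)

    if config.traits_path:
        traits = read_trait_table(config.traits_path)
        log_lines.append(f"trait_records = {len(traits)}")
        summary = trait_summary(traits, comparison=config.trait_comparison)
        log_lines.append(f"trait_summary_rows = {len(summary)}")
        outputs["trait_summary"] = out / "trait_summary.tsv"
        write_results(summary, outputs["trait_summary"])

    outputs["run_log"] = out / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    logger.info("pipeline finished: %d output files in %s", len(outputs), out)
    return outputs


def export_matrix(
    results: Iterable[RelativeExpression] | Iterable[GeneActionResult] | pd.DataFrame,
    value: str = "log2_rel_abundance",
    orientation: str = "genes_by_samples",
) -> pd.DataFrame:
    """Pivot a long result collection into a wide matrix for heatmap views.

    Rows are genes, columns are ``genotype:tissue`` composites (transposed
    for ``orientation="samples_by_genes"``); ``value`` names any numeric
    result column, typically ``log2_rel_abundance`` for expression results or
    ``da_ratio`` for gene-action results. Missing combinations stay as empty
    cells. The long table is recoverable by stacking the matrix.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = results if isinstance(results, pd.DataFrame) else records_to_frame(list(results))
    if df.empty:
        logger.warning("export_matrix: empty input, emitting header-only matrix")
        return pd.DataFrame()
    id_col = "genotype_id" if "genotype_id" in df.columns else "hybrid_id"
    if value not in df.columns:
        raise ValidationError(f"no column {value!r} in results "
                              f"(have: {', '.join(df.columns)})")
    df = df.copy()
    df["sample"] = df[id_col].astype(str) + ":" + df["tissue"].astype(str)
    wide = df.pivot_table(index="gene_id", columns="sample", values=value,
                          aggfunc="first", sort=True)
    wide.columns.name = None
    if orientation == "samples_by_genes":
        wide = wide.T
    return wide
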