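"""CT-level simulator with known true gene action, and recovery experiments.

The generator inverts the analysis pipeline. For each gene x tissue it draws
parental stress relative abundances (log2 values uniform over a configured
range, with a minimum log2 separation between the two parents of each trio),
imposes an exact true dominance ratio on the hybrid on the linear scale
(F1 = mu + r_true * a), converts each genotype's relative abundance to
noiseless CT values around a reference-gene baseline and a common control
dCT, and finally adds independent Gaussian noise (in cycles) to every
replicate CT — reference-gene rows included, one reference replicate set per
genotype x tissue x condition, shared across genes as on a real plate.

With zero noise the pipeline recovers every true d/a exactly (up to float
round-off), which pins down the whole composition; recovery under noise
measures how well the classifier separates additive, dominant and
over-dominant action at realistic replicate scatter.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io_tables import Condition, CtRecord, PedigreeEntry, Tissue
from .expression import expression_table
from .gene_action import (ActionClass, Direction, Scale, classify_gene_action,
                          da_ratio, gene_action_table)

logger = logging.getLogger("trioqpcr")

__all__ = ["SimulationConfig", "RecoveryReport", "simulate_trio_expression",
           "run_recovery"]

#: default true d/a cycle: ~20% additive, the rest split between partial /
#: complete dominance and over-dominance on both parental sides, echoing the
#: predominantly non-additive action seen in drought-stressed maize trios.
DEFAULT_TRUE_DA = (0.0, 0.25, 0.8, -0.8, 1.0, -1.0, 1.5, -2.0, 3.0, -5.0)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the CT simulator.

    Defaults emulate the reference panel design: 52 genes, five parent/hybrid
    trios, shoot and root tissue, stress and control arms, three technical
    replicates, a single abundant reference gene, and Gaussian replicate
    noise of 0.15 cycles on every CT.
    """

    n_genes: int = 52
    hybrids: Sequence[PedigreeEntry] = field(default_factory=lambda: _study())
    tissues: Sequence[Tissue | str] = (Tissue.SHOOT, Tissue.ROOT)
    true_da_spec: Mapping[str, float] | Sequence[float] = DEFAULT_TRUE_DA
    parental_log2_range: tuple[float, float] = (-3.0, 6.0)
    min_parent_log2_separation: float = 1.0
    reference_ct: float = 12.0       # cycles; abundant rRNA internal control
    control_dct: float = 10.0        # cycles; baseline target dCT in control
    ct_noise_sd: float = 0.15        # cycles
    n_replicates: int = 3
    seed: int = 0
    reference_gene_id: str = "18S"
    scale: Scale | str = Scale.LINEAR
    gene_ids: Sequence[str] | None = None
    max_redraws: int = 1000

    def __post_init__(self):
        self.tissues = tuple(Tissue(str(t).strip().lower()) if not isinstance(t, Tissue)
                             else t for t in self.tissues)
        self.scale = Scale(str(self.scale).strip().lower()) if not isinstance(
            self.scale, Scale) else self.scale
        self.hybrids = tuple(self.hybrids)
        problems = []
        if self.n_genes < 1:
            problems.append(f"n_genes must be >= 1, got {self.n_genes}")
        if not self.hybrids:
            problems.append("hybrids must be non-empty")
        if not self.tissues:
            problems.append("tissues must be non-empty")
        if self.ct_noise_sd < 0:
            problems.append(f"ct_noise_sd must be >= 0, got {self.ct_noise_sd}")
        if self.n_replicates < 1:
            problems.append(f"n_replicates must be >= 1, got {self.n_replicates}")
        lo, hi = self.parental_log2_range
        if not lo < hi:
            problems.append(f"parental_log2_range must be (lo, hi) with lo < hi, "
                            f"got {self.parental_log2_range}")
        if self.min_parent_log2_separation < 0:
            problems.append("min_parent_log2_separation must be >= 0")
        if self.min_parent_log2_separation >= (hi - lo):
            problems.append("min_parent_log2_separation exceeds the width of "
                            "parental_log2_range; parents cannot be drawn")
        if problems:
            raise ValidationError("invalid SimulationConfig", problems)
        if self.gene_ids is None:
            self.gene_ids = tuple(f"g{i + 1:03d}" for i in range(self.n_genes))
        else:
            self.gene_ids = tuple(str(g) for g in self.gene_ids)
            if len(self.gene_ids) != self.n_genes:
                raise ValidationError(
                    f"gene_ids has {len(self.gene_ids)} entries but "
                    f"n_genes = {self.n_genes}")

    def true_da_for(self, gene_index: int, gene_id: str) -> float:
        if isinstance(self.true_da_spec, Mapping):
            try:
                return float(self.true_da_spec[gene_id])
            except KeyError:
                raise ValidationError(
                    f"true_da_spec has no entry for gene {gene_id!r}") from None
        seq = tuple(self.true_da_spec)
        return float(seq[gene_index % len(seq)])

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        hybrids = data.get("hybrids", "study")
        if hybrids == "study" or hybrids is None:
            data["hybrids"] = _study()
        else:
            data["hybrids"] = [h if isinstance(h, PedigreeEntry)
                               else PedigreeEntry(**h) for h in hybrids]
        if "parental_log2_range" in data:
            data["parental_log2_range"] = tuple(data["parental_log2_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                "unknown SimulationConfig field(s)",
                sorted(repr(u) for u in unknown))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def _study() -> list[PedigreeEntry]:
    from .datasets import study_pedigree
    return study_pedigree()


def _parents_of(hybrids: Sequence[PedigreeEntry]) -> list[str]:
    seen: list[str] = []
    for h in hybrids:
        for p in (h.maternal_id, h.paternal_id):
            if p not in seen:
                seen.append(p)
    return seen


def _draw_panel(rng: np.random.Generator, config: SimulationConfig,
                parents: list[str], true_da: float) -> tuple[dict, dict]:
    """Draw one gene x tissue panel of parental log2 abundances satisfying the
    per-trio separation and hybrid-positivity constraints; returns
    (parent log2 map, hybrid linear-F1 map)."""
    lo, hi = config.parental_log2_range
    for _ in range(config.max_redraws):
        x = {p: rng.uniform(lo, hi) for p in parents}
        f1: dict[str, float] = {}
        ok = True
        for h in config.hybrids:
            xm, xp = x[h.maternal_id], x[h.paternal_id]
            if abs(xm - xp) < config.min_parent_log2_separation:
                ok = False
                break
            p1, p2 = 2.0 ** xm, 2.0 ** xp
            mu = (p1 + p2) / 2.0
            a = p1 - mu
            f = mu + true_da * a
            if f < 2.0 ** -12:  # hybrid abundance must stay positive
                ok = False
                break
            f1[h.hybrid_id] = f
        if ok:
            return x, f1
    raise ValidationError(
        f"could not draw parental abundances satisfying separation >= "
        f"{config.min_parent_log2_separation} and positive hybrid abundance "
        f"for true d/a = {true_da} within {config.max_redraws} redraws")


def simulate_trio_expression(
    config: SimulationConfig,
) -> tuple[list[CtRecord], pd.DataFrame]:
    """Generate a CT table and its truth table.

    Returns ``(records, truth)`` where ``truth`` has one row per
    gene x hybrid x tissue with columns gene_id, hybrid_id, tissue, true_da,
    true_class, true_direction, true_p_maternal, true_p_paternal, true_f1.
    All randomness comes from a single generator seeded with ``config.seed``;
    draws are ordered by (gene, tissue, genotype, condition, replicate), so a
    fixed config is bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    parents = _parents_of(config.hybrids)
    genotypes = parents + [h.hybrid_id for h in config.hybrids]
    records: list[CtRecord] = []
    truth_rows: list[dict] = []

    def noise() -> float:
        return float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd > 0 else 0.0

    for tissue in config.tissues:
        # linear stress abundance per genotype, per gene: filled below
        abundance: dict[str, list[float]] = {g: [] for g in genotypes}
        for gi, gene in enumerate(config.gene_ids):
            r_true = config.true_da_for(gi, gene)
            x, f1 = _draw_panel(rng, config, parents, r_true)
            for p in parents:
                abundance[p].append(2.0 ** x[p])
            for h in config.hybrids:
                abundance[h.hybrid_id].append(f1[h.hybrid_id])
                p1, p2 = 2.0 ** x[h.maternal_id], 2.0 ** x[h.paternal_id]
                mu, d, a, _ = da_ratio(p1, p2, f1[h.hybrid_id])
                klass, direction = classify_gene_action(d, a)
                truth_rows.append({
                    "gene_id": gene, "hybrid_id": h.hybrid_id,
                    "tissue": tissue.value, "true_da": r_true,
                    "true_class": klass.value,
                    "true_direction": direction.value,
                    "true_p_maternal": p1, "true_p_paternal": p2,
                    "true_f1": f1[h.hybrid_id],
                })
        # emit CT rows: per genotype, per condition, targets then one shared
        # reference-gene replicate set
        for genotype in genotypes:
            for condition in (Condition.STRESS, Condition.CONTROL):
                for gi, gene in enumerate(config.gene_ids):
                    dct = config.control_dct
                    if condition is Condition.STRESS:
                        dct = config.control_dct - math.log2(abundance[genotype][gi])
                    base = config.reference_ct + dct
                    for rep in range(1, config.n_replicates + 1):
                        records.append(CtRecord(
                            genotype_id=genotype, tissue=tissue,
                            condition=condition, gene_id=gene,
                            replicate=rep, ct=base + noise()))
                for rep in range(1, config.n_replicates + 1):
                    records.append(CtRecord(
                        genotype_id=genotype, tissue=tissue,
                        condition=condition,
                        gene_id=config.reference_gene_id,
                        replicate=rep, ct=config.reference_ct + noise()))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "hybrid_id", "tissue", "true_da", "true_class",
        "true_direction", "true_p_maternal", "true_p_paternal", "true_f1"])
    logger.info("simulated %d CT records, %d truth rows (seed=%d)",
                len(records), len(truth), config.seed)
    return records, truth


@dataclass
class RecoveryReport:
    """Outcome of a simulate -> analyze -> compare experiment."""

    config: SimulationConfig
    confusion: pd.DataFrame          # rows: true class:direction, cols: inferred
    recovery_rate: float             # trace / total
    per_class_rates: dict[str, float]
    n_total: int

    def summary(self) -> str:
        lines = [f"recovery_rate = {self.recovery_rate:.4f} "
                 f"(n = {self.n_total}, seed = {self.config.seed}, "
                 f"ct_noise_sd = {self.config.ct_noise_sd})"]
        for k in sorted(self.per_class_rates):
            lines.append(f"  {k}: {self.per_class_rates[k]:.4f}")
        return "\n".join(lines)


def run_recovery(config: SimulationConfig) -> RecoveryReport:
    """Simulate a dataset, run the full pipeline, and compare inferred
    (class, direction) calls to the imposed truth."""
    records, truth = simulate_trio_expression(config)
    expr = expression_table(records, config.reference_gene_id)
    results = gene_action_table(expr, config.hybrids, scale=config.scale)
    inferred = pd.DataFrame(
        [{"gene_id": r.gene_id, "hybrid_id": r.hybrid_id,
          "tissue": r.tissue.value,
          "inferred_class": r.action_class.value,
          "inferred_direction": r.direction.value,
          "inferred_da": r.da_ratio} for r in results])
    merged = truth.merge(inferred, on=["gene_id", "hybrid_id", "tissue"],
                         how="left", validate="one_to_one")
    if merged["inferred_class"].isna().any():
        missing = int(merged["inferred_class"].isna().sum())
        raise ValidationError(
            f"pipeline lost {missing} of {len(merged)} simulated trios")
    t_lab = merged["true_class"] + ":" + merged["true_direction"]
    i_lab = merged["inferred_class"] + ":" + merged["inferred_direction"]
    confusion = pd.crosstab(t_lab, i_lab, dropna=False)
    match = (t_lab == i_lab)
    per_class = {lab: float(match[t_lab == lab].mean())
                 for lab in sorted(t_lab.unique())}
    return RecoveryReport(config=config, confusion=confusion,
                          recovery_rate=float(match.mean()),
                          per_class_rates=per_class, n_total=len(merged))
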