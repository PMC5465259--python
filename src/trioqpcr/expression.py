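"""Reference-normalized relative expression via the comparative-CT method.

For each genotype x tissue x condition sample, replicate CT values are
averaged on the CT scale, target genes are normalized against the mean CT
of a single reference gene measured in the same sample
(dCT = CT_target - CT_reference), the stress and control conditions are
contrasted (ddCT = dCT_stress - dCT_control), and the relative transcript
abundance under stress is 2**(-ddCT). Perfect per-cycle doubling is assumed
(no amplification-efficiency correction); down-regulation appears as a
relative abundance in (0, 1), i.e. log2 abundance < 0.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ComputationError
from .io_tables import CtRecord, Tissue, records_to_frame, _parse_enum, _clean_str, _finite_float

logger = logging.getLogger("trioqpcr")

__all__ = [
    "RelativeExpression", "aggregate_replicates", "delta_ct",
    "delta_delta_ct", "fold_change", "expression_table",
]


@dataclass(frozen=True)
class RelativeExpression:
    """Stress-vs-control relative abundance of one gene in one
    genotype x tissue, on the fold scale and its log2."""

    genotype_id: str
    tissue: Tissue
    gene_id: str
    dct_stress: float
    dct_control: float
    ddct: float
    rel_abundance: float
    log2_rel_abundance: float

    def __post_init__(self):
        object.__setattr__(self, "genotype_id", _clean_str(self.genotype_id, "genotype_id"))
        object.__setattr__(self, "gene_id", _clean_str(self.gene_id, "gene_id"))
        object.__setattr__(self, "tissue", _parse_enum(Tissue, self.tissue, "tissue"))
        for f in ("dct_stress", "dct_control", "ddct", "rel_abundance",
                  "log2_rel_abundance"):
            object.__setattr__(self, f, _finite_float(getattr(self, f), f))


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ComputationError(f"{name}: non-finite input {v!r}")


def delta_ct(target_ct_mean: float, reference_ct_mean: float) -> float:
    """Normalize a target CT against the reference-gene CT of the same sample."""
    _require_finite("delta_ct", target_ct_mean, reference_ct_mean)
    return target_ct_mean - reference_ct_mean


def delta_delta_ct(dct_stress: float, dct_control: float) -> float:
    """Contrast the stress dCT against the control dCT."""
    _require_finite("delta_delta_ct", dct_stress, dct_control)
    return dct_stress - dct_control


def fold_change(ddct: float) -> float:
    """Relative abundance 2**(-ddCT); strictly positive, 1 means no change."""
    _require_finite("fold_change", ddct)
    return 2.0 ** (-ddct)


def aggregate_replicates(records: Iterable[CtRecord]) -> pd.DataFrame:
    """Mean CT per (genotype_id, tissue, condition, gene_id) group.

    Returns a frame with columns ``ct_mean``, ``ct_sd`` (sample standard
    deviation, 0.0 when a single replicate) and ``n_replicates``.
    """
    df = records_to_frame(list(records))
    if df.empty:
        return pd.DataFrame(
            columns=["genotype_id", "tissue", "condition", "gene_id",
                     "ct_mean", "ct_sd", "n_replicates"])
    g = df.groupby(["genotype_id", "tissue", "condition", "gene_id"],
                   sort=True)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n_replicates="size").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    return out


def expression_table(ct_records: Iterable[CtRecord],
                     reference_gene_id: str) -> list[RelativeExpression]:
    """Full comparative-CT composition over a CT table.

    One result per genotype x tissue x target gene that has complete stress
    and control data (target and reference); incomplete combinations are
    omitted with a logged warning naming them. Output order is sorted by
    (genotype_id, tissue, gene_id), so the result is invariant to the input
    row order.
    """
    ref = reference_gene_id.strip()
    agg = aggregate_replicates(ct_records)
    if agg.empty:
        return []
    is_ref = agg["gene_id"] == ref
    ref_ct = (agg[is_ref]
              .set_index(["genotype_id", "tissue", "condition"])["ct_mean"])
    targets = agg[~is_ref].copy()

    sample_key = list(zip(targets["genotype_id"], targets["tissue"],
                          targets["condition"]))
    has_ref = [k in ref_ct.index for k in sample_key]
    dropped = targets[~np.asarray(has_ref, dtype=bool)]
    for g, t, c in sorted(set(zip(dropped["genotype_id"], dropped["tissue"],
                                  dropped["condition"]))):
        logger.warning(
            "sample genotype=%s tissue=%s condition=%s has no reference-gene "
            "CT; its genes are omitted", g, t, c)
    targets = targets[np.asarray(has_ref, dtype=bool)].copy()
    if targets.empty:
        return []
    targets["dct"] = [
        delta_ct(ct, ref_ct.loc[(g, t, c)])
        for ct, g, t, c in zip(targets["ct_mean"], targets["genotype_id"],
                               targets["tissue"], targets["condition"])
    ]
    wide = targets.pivot_table(index=["genotype_id", "tissue", "gene_id"],
                               columns="condition", values="dct",
                               aggfunc="first")
    results: list[RelativeExpression] = []
    for (g, t, gene), row in wide.sort_index().iterrows():
        dct_s = row.get("stress", np.nan)
        dct_c = row.get("control", np.nan)
        if not (np.isfinite(dct_s) and np.isfinite(dct_c)):
            missing = "control" if np.isfinite(dct_s) else "stress"
            logger.warning(
                "gene %s in genotype=%s tissue=%s lacks %s-condition CT; "
                "omitted", gene, g, t, missing)
            continue
        ddct = delta_delta_ct(float(dct_s), float(dct_c))
        rel = fold_change(ddct)
        results.append(RelativeExpression(
            genotype_id=g, tissue=t, gene_id=gene,
            dct_stress=float(dct_s), dct_control=float(dct_c),
            ddct=ddct, rel_abundance=rel, log2_rel_abundance=-ddct))
    return results
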