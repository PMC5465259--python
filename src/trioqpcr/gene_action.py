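"""Mid-parent gene-action analysis of hybrid expression (the d/a ratio).

The expression level of a gene is treated as a quantitative phenotype of a
parent/hybrid trio. With P1 the maternal parent's phenotype, P2 the paternal
parent's and F1 the hybrid's:

    mu  = (P1 + P2) / 2        mid-parent value
    d   = F1 - mu              dominance deviation
    a   = P1 - mu              additive deviation (maternal minus mid-parent)
    r   = d / a                dominance ratio (defined when |a| > epsilon)

Fixed points: r = 0 when F1 equals the mid-parent (purely additive),
r = +1 when F1 equals the maternal parent (complete maternal dominance),
r = -1 when F1 equals the paternal parent (complete paternal dominance).
|r| > 1 means F1 falls outside the parental range (over-dominance). Because
``a`` carries the sign of the maternal-paternal contrast, a positive r always
marks deviation toward the maternal parent and a negative r toward the
paternal parent, whichever parent expresses higher.

Classification (defaults): additive for |r| <= 0.5 (closed interval),
dominant for 0.5 < |r| <= 1, over-dominant for |r| > 1; direction is
maternal for r > 0, paternal for r < 0, none for additive. When the hybrid
falls *below* both parents the over-dominance is credited to the nearer
(lower-expressing) parent and flagged ``below_range``.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ComputationError
from .io_tables import (GeneAnnotation, PedigreeEntry, Tissue, _clean_str,
                        _parse_enum, records_to_frame)
from .expression import RelativeExpression

logger = logging.getLogger("trioqpcr")

__all__ = [
    "ActionClass", "Direction", "Scale", "GeneActionResult", "InfluenceTally",
    "mid_parent", "da_ratio", "classify_gene_action", "gene_action_table",
    "tally_influence", "nonadditive_fraction",
    "DEFAULT_ADDITIVE_HALFWIDTH", "DEFAULT_DOMINANCE_BOUND", "DEFAULT_EPSILON",
]

DEFAULT_ADDITIVE_HALFWIDTH = 0.5
DEFAULT_DOMINANCE_BOUND = 1.0
DEFAULT_EPSILON = 1e-9


class ActionClass(str, enum.Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    OVERDOMINANT = "overdominant"
    UNDETERMINED = "undetermined"


class Direction(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    NONE = "none"


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


@dataclass(frozen=True)
class GeneActionResult:
    """Gene action of one gene in one hybrid x tissue."""

    hybrid_id: str
    tissue: Tissue
    gene_id: str
    category: str
    p_maternal: float
    p_paternal: float
    f1: float
    mu: float
    d: float
    a: float
    da_ratio: float  # NaN when |a| <= epsilon (flagged undefined)
    action_class: ActionClass
    direction: Direction
    scale: Scale
    below_range: bool

    def __post_init__(self):
        object.__setattr__(self, "tissue", _parse_enum(Tissue, self.tissue, "tissue"))
        object.__setattr__(self, "action_class",
                           _parse_enum(ActionClass, self.action_class, "action_class"))
        object.__setattr__(self, "direction",
                           _parse_enum(Direction, self.direction, "direction"))
        object.__setattr__(self, "scale", _parse_enum(Scale, self.scale, "scale"))


@dataclass(frozen=True)
class InfluenceTally:
    """Counts of parental influence within one scope (overall or a group)."""

    scope: str
    n_maternal: int
    n_paternal: int
    n_additive: int
    n_undetermined: int
    n_total: int

    def __post_init__(self):
        s = self.n_maternal + self.n_paternal + self.n_additive + self.n_undetermined
        if s != self.n_total:
            raise ComputationError(
                f"tally {self.scope!r}: counts {s} do not sum to total {self.n_total}")


def mid_parent(p_maternal: float, p_paternal: float) -> float:
    """Mid-parent value: arithmetic mean of the two parental phenotypes."""
    for v in (p_maternal, p_paternal):
        if not math.isfinite(v):
            raise ComputationError(f"mid_parent: non-finite input {v!r}")
    return (p_maternal + p_paternal) / 2.0


def da_ratio(p_maternal: float, p_paternal: float, f1: float,
             epsilon: float = DEFAULT_EPSILON) -> tuple[float, float, float, float]:
    """Return (mu, d, a, r) for a trio; r is NaN when |a| <= epsilon.

    The sign convention a = maternal - mid-parent makes a positive ratio mean
    deviation toward the maternal parent regardless of which parent is the
    higher expresser.
    """
    if epsilon <= 0:
        raise ComputationError(f"epsilon must be > 0, got {epsilon}")
    if not math.isfinite(f1):
        raise ComputationError(f"da_ratio: non-finite F1 {f1!r}")
    mu = mid_parent(p_maternal, p_paternal)
    d = f1 - mu
    a = p_maternal - mu
    r = d / a if abs(a) > epsilon else math.nan
    return mu, d, a, r


def classify_gene_action(
    d: float, a: float,
    additive_halfwidth: float = DEFAULT_ADDITIVE_HALFWIDTH,
    dominance_bound: float = DEFAULT_DOMINANCE_BOUND,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[ActionClass, Direction]:
    """Classify one trio's gene action from its d and a deviations.

    Degenerate parents (|a| <= epsilon): additive when the hybrid also sits
    at the (common) parental value (|d| <= epsilon), otherwise undetermined —
    the ratio has no information there.
    """
    if not 0 < additive_halfwidth < dominance_bound:
        raise ComputationError(
            f"need 0 < additive_halfwidth < dominance_bound, got "
            f"{additive_halfwidth}, {dominance_bound}")
    if abs(a) <= epsilon:
        if abs(d) <= epsilon:
            return ActionClass.ADDITIVE, Direction.NONE
        return ActionClass.UNDETERMINED, Direction.NONE
    r = d / a
    if abs(r) <= additive_halfwidth:
        return ActionClass.ADDITIVE, Direction.NONE
    direction = Direction.MATERNAL if r > 0 else Direction.PATERNAL
    if abs(r) <= dominance_bound:
        return ActionClass.DOMINANT, direction
    return ActionClass.OVERDOMINANT, direction


def _phenotype_column(scale: Scale) -> str:
    return "rel_abundance" if scale is Scale.LINEAR else "log2_rel_abundance"


def gene_action_table(
    expr: Iterable[RelativeExpression],
    pedigree: Iterable[PedigreeEntry],
    scale: Scale | str = Scale.LINEAR,
    annotation: Iterable[GeneAnnotation] | None = None,
    additive_halfwidth: float = DEFAULT_ADDITIVE_HALFWIDTH,
    dominance_bound: float = DEFAULT_DOMINANCE_BOUND,
    epsilon: float = DEFAULT_EPSILON,
) -> list[GeneActionResult]:
    """Compute gene action for every hybrid x tissue x gene with a complete trio.

    ``scale`` selects the expression phenotype: the linear relative abundance
    (default) or its log2. Trios with a missing member are omitted with a
    warning; hybrids in the pedigree absent from the expression data are
    skipped with a warning. ``annotation`` (optional) fills the functional
    category column.
    """
    scale = _parse_enum(Scale, scale, "scale")
    pheno_col = _phenotype_column(scale)
    cat = {a.gene_id: a.category.value for a in annotation} if annotation else {}
    df = records_to_frame(list(expr))
    results: list[GeneActionResult] = []
    if df.empty:
        return results
    pheno = df.set_index(["genotype_id", "tissue", "gene_id"])[pheno_col]

    by_genotype = set(df["genotype_id"])
    for entry in pedigree:
        if entry.hybrid_id not in by_genotype:
            logger.warning("hybrid %s has no expression data; skipped",
                           entry.hybrid_id)
            continue
        sub = df[df["genotype_id"] == entry.hybrid_id]
        for (tissue, gene), _ in sub.groupby(["tissue", "gene_id"], sort=True):
            try:
                f1 = float(pheno.loc[(entry.hybrid_id, tissue, gene)])
                p1 = float(pheno.loc[(entry.maternal_id, tissue, gene)])
                p2 = float(pheno.loc[(entry.paternal_id, tissue, gene)])
            except KeyError:
                logger.warning(
                    "trio %s (%s x %s) incomplete for gene %s tissue %s; "
                    "omitted", entry.hybrid_id, entry.maternal_id,
                    entry.paternal_id, gene, tissue)
                continue
            mu, d, a, r = da_ratio(p1, p2, f1, epsilon=epsilon)
            action, direction = classify_gene_action(
                d, a, additive_halfwidth, dominance_bound, epsilon)
            below = bool(action is ActionClass.OVERDOMINANT
                         and f1 < min(p1, p2))
            results.append(GeneActionResult(
                hybrid_id=entry.hybrid_id, tissue=tissue, gene_id=gene,
                category=cat.get(gene, ""), p_maternal=p1, p_paternal=p2,
                f1=f1, mu=mu, d=d, a=a, da_ratio=r, action_class=action,
                direction=direction, scale=scale, below_range=below))
    return results


def tally_influence(
    results: Iterable[GeneActionResult],
    by: str | Sequence[str] | None = None,
    categories: Mapping[str, str] | None = None,
) -> list[InfluenceTally]:
    """Count maternal / paternal / additive / undetermined calls.

    ``by`` is None for one overall tally, or one of / a list of result fields
    (e.g. ``"hybrid_id"``, ``"tissue"``, ``"category"``) for per-group
    tallies. Group tallies always sum to the overall tally (conservation).
    """
    results = list(results)
    if not results:
        return []
    df = records_to_frame(results)
    if categories:
        df["category"] = df["gene_id"].map(categories).fillna(df["category"])

    def _tally(scope: str, sub: pd.DataFrame) -> InfluenceTally:
        n_mat = int((sub["direction"] == Direction.MATERNAL.value).sum())
        n_pat = int((sub["direction"] == Direction.PATERNAL.value).sum())
        n_add = int((sub["action_class"] == ActionClass.ADDITIVE.value).sum())
        n_und = int((sub["action_class"] == ActionClass.UNDETERMINED.value).sum())
        return InfluenceTally(scope=scope, n_maternal=n_mat, n_paternal=n_pat,
                              n_additive=n_add, n_undetermined=n_und,
                              n_total=len(sub))

    if by is None:
        return [_tally("overall", df)]
    keys = [by] if isinstance(by, str) else list(by)
    tallies = []
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        scope = ",".join(f"{k}={v}" for k, v in zip(keys, key))
        tallies.append(_tally(scope, sub))
    return tallies


def nonadditive_fraction(results: Iterable[GeneActionResult]) -> float:
    """Fraction of calls that are dominant or over-dominant (toward either
    parent); NaN for an empty collection."""
    results = list(results)
    if not results:
        return math.nan
    n = sum(r.action_class in (ActionClass.DOMINANT, ActionClass.OVERDOMINANT)
            for r in results)
    return n / len(results)
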