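"""Reading, validation and writing of the pipeline's delimited tables.

All tables are plain text, tab- or comma-delimited (auto-detected from the
``.tsv`` / ``.csv`` extension), UTF-8, ``.`` decimal separator. Enum tokens
are matched case- and whitespace-insensitively because these tables are
typically hand-curated lab exports.

Fixed column names:

====================  ======================================================
table                 columns
====================  ======================================================
CT table              genotype_id, tissue, condition, gene_id, replicate, ct
pedigree              hybrid_id, maternal_id, paternal_id, tolerance_class
gene annotation       gene_id, symbol, chromosome, category
trait table           genotype_id, condition, day, replicate, fresh_weight,
                      dry_weight, turgid_weight, root_length,
                      spad_chlorophyll  (weights optional)
====================  ======================================================
"""
from __future__ import annotations

import dataclasses
import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Type, TypeVar

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("trioqpcr")

__all__ = [
    "Tissue", "Condition", "GeneCategory", "ToleranceClass",
    "CtRecord", "PedigreeEntry", "GeneAnnotation",
    "read_ct_table", "read_pedigree", "read_annotation", "read_trait_table",
    "write_results", "records_to_frame", "frame_to_records", "read_results",
]


class Tissue(str, enum.Enum):
    SHOOT = "shoot"
    ROOT = "root"


class Condition(str, enum.Enum):
    STRESS = "stress"
    CONTROL = "control"


class GeneCategory(str, enum.Enum):
    STOMATAL_REGULATION = "stomatal_regulation"
    ROOT_DEVELOPMENT = "root_development"
    ROS_SCAVENGING = "ros_scavenging"
    HORMONE_SIGNALING = "hormone_signaling"
    PHOTOSYNTHESIS = "photosynthesis"
    SUGAR_METABOLISM = "sugar_metabolism"


class ToleranceClass(str, enum.Enum):
    TOLERANT = "tolerant"
    MODERATE = "moderate"
    SENSITIVE = "sensitive"


E = TypeVar("E", bound=enum.Enum)
R = TypeVar("R")


def _parse_enum(cls: Type[E], token: object, field: str) -> E:
    if isinstance(token, cls):
        return token
    norm = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return cls(norm)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown {field} token {token!r} (allowed: {allowed})"
        ) from None


def _clean_str(value: object, field: str) -> str:
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        raise ValidationError(f"{field} is empty")
    return s


def _finite_float(value: object, field: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{field} is not numeric: {value!r}") from None
    if not math.isfinite(x):
        raise ValidationError(f"{field} is not finite: {value!r}")
    return x


def _positive_int(value: object, field: str) -> int:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{field} is not an integer: {value!r}") from None
    if not math.isfinite(x) or x != int(x):
        raise ValidationError(f"{field} is not an integer: {value!r}")
    i = int(x)
    if i < 1:
        raise ValidationError(f"{field} must be >= 1, got {i}")
    return i


@dataclass(frozen=True)
class CtRecord:
    """One raw qPCR observation: a cycle-threshold value for one
    genotype x tissue x condition x gene x replicate."""

    genotype_id: str
    tissue: Tissue
    condition: Condition
    gene_id: str
    replicate: int
    ct: float

    def __post_init__(self):
        object.__setattr__(self, "genotype_id", _clean_str(self.genotype_id, "genotype_id"))
        object.__setattr__(self, "gene_id", _clean_str(self.gene_id, "gene_id"))
        object.__setattr__(self, "tissue", _parse_enum(Tissue, self.tissue, "tissue"))
        object.__setattr__(self, "condition", _parse_enum(Condition, self.condition, "condition"))
        object.__setattr__(self, "replicate", _positive_int(self.replicate, "replicate"))
        ct = _finite_float(self.ct, "ct")
        if ct <= 0:
            raise ValidationError(f"ct must be > 0, got {ct}")
        object.__setattr__(self, "ct", ct)


@dataclass(frozen=True)
class PedigreeEntry:
    """Hybrid and its maternal (listed first in a cross) and paternal parents."""

    hybrid_id: str
    maternal_id: str
    paternal_id: str
    tolerance_class: ToleranceClass | None = None

    def __post_init__(self):
        object.__setattr__(self, "hybrid_id", _clean_str(self.hybrid_id, "hybrid_id"))
        object.__setattr__(self, "maternal_id", _clean_str(self.maternal_id, "maternal_id"))
        object.__setattr__(self, "paternal_id", _clean_str(self.paternal_id, "paternal_id"))
        if self.tolerance_class is not None and not (
            isinstance(self.tolerance_class, float) and math.isnan(self.tolerance_class)
        ):
            object.__setattr__(
                self, "tolerance_class",
                _parse_enum(ToleranceClass, self.tolerance_class, "tolerance_class"),
            )
        else:
            object.__setattr__(self, "tolerance_class", None)
        if self.maternal_id == self.paternal_id:
            raise ValidationError(
                f"hybrid {self.hybrid_id}: maternal and paternal parent are both "
                f"{self.maternal_id!r}"
            )
        if self.hybrid_id in (self.maternal_id, self.paternal_id):
            raise ValidationError(
                f"hybrid {self.hybrid_id} coincides with one of its parents"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Candidate gene with its chromosome and drought functional category."""

    gene_id: str
    symbol: str
    chromosome: int
    category: GeneCategory

    def __post_init__(self):
        object.__setattr__(self, "gene_id", _clean_str(self.gene_id, "gene_id"))
        object.__setattr__(self, "symbol", _clean_str(self.symbol, "symbol"))
        object.__setattr__(self, "chromosome", _positive_int(self.chromosome, "chromosome"))
        if not 1 <= self.chromosome <= 10:
            raise ValidationError(
                f"gene {self.gene_id}: chromosome must be in 1..10, got {self.chromosome}"
            )
        object.__setattr__(self, "category", _parse_enum(GeneCategory, self.category, "category"))


# ---------------------------------------------------------------------------
# frame <-> records helpers

def _sep_for(path: Path) -> str | None:
    ext = path.suffix.lower()
    if ext == ".tsv":
        return "\t"
    if ext == ".csv":
        return ","
    return None  # sniff


def _read_frame(path: str | Path, columns: Sequence[str],
                optional: Sequence[str] = ()) -> pd.DataFrame | None:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    sep = _sep_for(path)
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        else:
            df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return None
    df.columns = [str(c).strip() for c in df.columns]
    required = [c for c in columns if c not in optional]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _build_records(df: pd.DataFrame, cls: Type[R], fields: Sequence[str]) -> list[R]:
    """Construct one record per row, collecting every offending row."""
    records: list[R] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        kwargs = {f: getattr(row, f) for f in fields if hasattr(row, f)}
        try:
            records.append(cls(**kwargs))
        except ValidationError as exc:
            problems.append(f"line {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) for {cls.__name__}", problems
        )
    return records


def records_to_frame(records: Iterable[object]) -> pd.DataFrame:
    """Convert a sequence of record dataclasses to a DataFrame with the
    dataclass field order as the column order."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    fields = [f.name for f in dataclasses.fields(records[0])]
    rows = []
    for r in records:
        row = {}
        for f in fields:
            v = getattr(r, f)
            row[f] = v.value if isinstance(v, enum.Enum) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=fields)


def frame_to_records(df: pd.DataFrame, cls: Type[R]) -> list[R]:
    """Rebuild record dataclasses from a frame (the inverse of
    :func:`records_to_frame`); enum and numeric coercion happens in the
    record constructors."""
    fields = [f.name for f in dataclasses.fields(cls)]
    return _build_records(df, cls, fields)


# ---------------------------------------------------------------------------
# readers

def read_ct_table(path: str | Path, reference_gene_id: str) -> list[CtRecord]:
    """Read and validate a long-format CT table.

    Every (genotype, tissue, condition, replicate) group must contain at
    least one row for ``reference_gene_id``; groups without one are reported
    together in a single :class:`ValidationError`.
    """
    cols = ["genotype_id", "tissue", "condition", "gene_id", "replicate", "ct"]
    df = _read_frame(path, cols)
    if df is None or df.empty:
        logger.warning("CT table %s is empty", path)
        return []
    ct_num = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct_num.isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad)
        raise ParseError(f"{path}: non-numeric ct value(s) at line(s) {lines}")
    records = _build_records(df, CtRecord, cols)
    # reference-gene coverage per sample x replicate group
    ref = reference_gene_id.strip()
    groups: dict[tuple, bool] = {}
    for r in records:
        key = (r.genotype_id, r.tissue.value, r.condition.value, r.replicate)
        groups[key] = groups.get(key, False) or (r.gene_id == ref)
    orphans = [k for k, has_ref in groups.items() if not has_ref]
    if orphans:
        raise ValidationError(
            f"{path}: {len(orphans)} group(s) lack reference gene {ref!r} rows",
            [f"genotype={g} tissue={t} condition={c} replicate={rep}"
             for g, t, c, rep in sorted(orphans)],
        )
    logger.info("read %d CT records from %s", len(records), path)
    return records


def read_pedigree(path: str | Path) -> list[PedigreeEntry]:
    """Read the hybrid -> (maternal, paternal) pedigree table."""
    cols = ["hybrid_id", "maternal_id", "paternal_id", "tolerance_class"]
    df = _read_frame(path, cols, optional=("tolerance_class",))
    if df is None or df.empty:
        logger.warning("pedigree table %s is empty", path)
        return []
    entries = _build_records(df, PedigreeEntry, cols)
    seen: dict[str, int] = {}
    dups = []
    for e in entries:
        seen[e.hybrid_id] = seen.get(e.hybrid_id, 0) + 1
    dups = [h for h, n in seen.items() if n > 1]
    if dups:
        raise ValidationError(
            f"{path}: duplicate hybrid_id(s)", [repr(h) for h in sorted(dups)]
        )
    logger.info("read %d pedigree entries from %s", len(entries), path)
    return entries


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the candidate-gene annotation table."""
    cols = ["gene_id", "symbol", "chromosome", "category"]
    df = _read_frame(path, cols)
    if df is None or df.empty:
        logger.warning("annotation table %s is empty", path)
        return []
    annos = _build_records(df, GeneAnnotation, cols)
    seen: dict[str, int] = {}
    for a in annos:
        seen[a.gene_id] = seen.get(a.gene_id, 0) + 1
    dups = [g for g, n in seen.items() if n > 1]
    if dups:
        raise ValidationError(
            f"{path}: duplicate gene_id(s)", [repr(g) for g in sorted(dups)]
        )
    logger.info("read %d gene annotations from %s", len(annos), path)
    return annos


def read_trait_table(path: str | Path):
    """Read the physiological trait table (see :mod:`trioqpcr.traits`)."""
    from .traits import TraitRecord  # local import to avoid a cycle

    cols = ["genotype_id", "condition", "day", "replicate",
            "fresh_weight", "dry_weight", "turgid_weight",
            "root_length", "spad_chlorophyll"]
    optional = ("fresh_weight", "dry_weight", "turgid_weight",
                "root_length", "spad_chlorophyll")
    df = _read_frame(path, cols, optional=optional)
    if df is None or df.empty:
        logger.warning("trait table %s is empty", path)
        return []
    for c in optional:
        if c not in df.columns:
            df[c] = None
    records = _build_records(df, TraitRecord, cols)
    logger.info("read %d trait records from %s", len(records), path)
    return records


# ---------------------------------------------------------------------------
# writer

def write_results(records, path: str | Path, record_type: Type | None = None) -> None:
    """Write any record collection (or DataFrame) as a delimited file.

    Column order is the dataclass field order; floats are written with 12
    significant digits so a write/read round-trip is lossless at that
    precision. Parent directories are created as needed. An empty collection
    yields a header-only file when ``record_type`` is given (otherwise an
    empty file).
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
        if df.empty and record_type is not None:
            df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(record_type)])
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _sep_for(path) or "\t"
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    logger.info("wrote %d rows to %s", len(df), path)


def read_results(path: str | Path, cls: Type[R]) -> list[R]:
    """Read back a file written by :func:`write_results` into records of ``cls``."""
    path = Path(path)
    sep = _sep_for(path) or "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    return frame_to_records(df, cls)
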