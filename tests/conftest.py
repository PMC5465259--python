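"""Shared fixtures: tiny in-memory study tables written to tmp paths."""
from __future__ import annotations

import math
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from trioqpcr import CtRecord

settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("ci")

REF = "18S"


def ct_rows(genotype, tissue, condition, gene, cts):
    return [f"{genotype}\t{tissue}\t{condition}\t{gene}\t{i}\t{ct}"
            for i, ct in enumerate(cts, start=1)]


def write_ct_table(path: Path, rows: list[str]) -> Path:
    header = "genotype_id\ttissue\tcondition\tgene_id\treplicate\tct"
    path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
    return path


def ct_records_for_sample(genotype, tissue, rel_abundance: dict[str, float],
                          reference_ct=12.0, control_dct=10.0, n_replicates=3):
    """Noiseless CT records realizing given stress rel-abundances per gene."""
    records = []
    for condition in ("stress", "control"):
        for gene, rel in rel_abundance.items():
            dct = control_dct - (math.log2(rel) if condition == "stress" else 0.0)
            for rep in range(1, n_replicates + 1):
                records.append(CtRecord(genotype, tissue, condition, gene,
                                        rep, reference_ct + dct))
        for rep in range(1, n_replicates + 1):
            records.append(CtRecord(genotype, tissue, condition, REF,
                                    rep, reference_ct))
    return records


@pytest.fixture
def small_ct_file(tmp_path) -> Path:
    """One genotype x shoot, one target gene + reference, 3 replicates,
    both conditions (12 rows)."""
    rows = []
    rows += ct_rows("P1", "shoot", "stress", "gA", [24.9, 25.0, 25.1])
    rows += ct_rows("P1", "shoot", "stress", REF, [15.0, 15.0, 15.0])
    rows += ct_rows("P1", "shoot", "control", "gA", [26.0, 26.0, 26.0])
    rows += ct_rows("P1", "shoot", "control", REF, [15.0, 15.0, 15.0])
    return write_ct_table(tmp_path / "ct.tsv", rows)


@pytest.fixture
def study_tables(tmp_path):
    """Built-in pedigree + annotation written as TSV files."""
    from trioqpcr.datasets import write_study_tables
    return write_study_tables(tmp_path / "study")


@pytest.fixture
def trait_file(tmp_path) -> Path:
    header = ("genotype_id\tcondition\tday\treplicate\tfresh_weight\t"
              "dry_weight\tturgid_weight\troot_length\tspad_chlorophyll")
    rows = [
        # genotype A: control RL 20, stress RL 18 (10% reduction); RWC 90 -> 75
        "A\tcontrol\t5\t1\t8.8\t2.0\t10.0\t20.0\t40.0",
        "A\tcontrol\t5\t2\t9.6\t2.0\t10.0\t20.0\t40.0",
        "A\tstress\t1\t1\t8.0\t2.0\t10.0\t19.0\t40.0",
        "A\tstress\t5\t1\t8.0\t2.0\t10.0\t18.0\t35.6",
        # genotype B: stress only (skipped in stress_vs_control)
        "B\tstress\t5\t1\t6.0\t2.0\t10.0\t15.0\t30.0",
    ]
    p = tmp_path / "traits.tsv"
    p.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
    return p
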