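"""Built-in reference panel: the study design the simulator emulates.

Five subtropical maize F1 hybrids with their parental inbreds (the maternal
parent is listed first in each cross) and 52 drought-responsive candidate
genes grouped into six functional categories (10 stomatal regulation,
10 root development, 10 ROS scavenging, 12 hormone signaling,
5 photosynthesis, 5 sugar metabolism).
"""
from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from .io_tables import GeneAnnotation, PedigreeEntry, frame_to_records

STUDY_PEDIGREE_TSV = """\
hybrid_id\tmaternal_id\tpaternal_id\ttolerance_class
ADWLH2\tHKI1105\tCML425\ttolerant
HM8\tHKI1105\tHKI161\tmoderate
HM9\tHKI1105\tHKI1128\tmoderate
PMH1\tLM13\tLM14\tsensitive
PMH3\tLM17\tLM14\tsensitive
"""

CANDIDATE_GENES_TSV = """\
gene_id\tsymbol\tchromosome\tcategory
GRMZM2G069365\tzhd17\t4\tstomatal_regulation
GRMZM2G071112\tzhd13\t7\tstomatal_regulation
GRMZM2G089619\tzhd15\t2\tstomatal_regulation
GRMZM2G122479\tme2\t6\tstomatal_regulation
GRMZM2G407181\tnced2\t1\tstomatal_regulation
GRMZM5G858784\tnced3\t3\tstomatal_regulation
GRMZM2G159724\tme6\t3\tstomatal_regulation
GRMZM2G053384\tPRC protein\t2\tstomatal_regulation
GRMZM2G102429\tu-box\t2\tstomatal_regulation
GRMZM2G060465\tereb155\t4\tstomatal_regulation
GRMZM2G015605\tnac1\t10\troot_development
GRMZM2G028648\tnac2\t6\troot_development
GRMZM2G090576\tnac3\t5\troot_development
GRMZM2G091819\tflavin monooxygenase\t10\troot_development
GRMZM2G104400\tnactf38\t8\troot_development
GRMZM2G371345\tV-type PPase H+ pump\t10\troot_development
GRMZM2G003466\tereb101\t1\troot_development
GRMZM2G124037\tdbf3\t2\troot_development
GRMZM2G432571\tNBS-IRR partial\t5\troot_development
GRMZM2G134073\tnac68\t8\troot_development
GRMZM2G025992\tsod2\t7\tros_scavenging
GRMZM2G054559\tpld1\t3\tros_scavenging
GRMZM2G066120\tmkkk11\t1\tros_scavenging
GRMZM2G071021\taldh3\t3\tros_scavenging
GRMZM2G140667\tapx2\t2\tros_scavenging
GRMZM2G172322\tgsr1\t1\tros_scavenging
GRMZM5G884600\tGPx\t10\tros_scavenging
GRMZM2G059991\tsod3\t6\tros_scavenging
GRMZM5G822829\tBHLH\t10\tros_scavenging
GRMZM2G367411\tmkk6\t5\tros_scavenging
GRMZM2G056120\tartf11\t3\thormone_signaling
GRMZM2G057935\tphyC1\t1\thormone_signaling
GRMZM2G066867\tsnrkII10\t5\thormone_signaling
GRMZM5G867568\tMAPKK3\t3\thormone_signaling
GRMZM2G112240\tprh1\t4\thormone_signaling
GRMZM2G180555\tMKKK10\t9\thormone_signaling
GRMZM2G305066\tMKKK18\t8\thormone_signaling
GRMZM2G117851\tbzip1\t3\thormone_signaling
GRMZM2G083717\twrky14\t1\thormone_signaling
GRMZM2G152661\tcamta5\t10\thormone_signaling
GRMZM2G008250\tNFY-A\t1\thormone_signaling
GRMZM2G172327\tmyb14\t7\thormone_signaling
GRMZM2G012397\tpsa6\t7\tphotosynthesis
GRMZM2G078409\tploc2\t2\tphotosynthesis
GRMZM2G122337\tferredoxin 1\t6\tphotosynthesis
GRMZM2G162200\trca1\t4\tphotosynthesis
GRMZM2G162282\trca3\t4\tphotosynthesis
GRMZM2G016890\tSbe2A\t10\tsugar_metabolism
GRMZM2G058310\tamyb5\t7\tsugar_metabolism
GRMZM2G130043\tss5\t4\tsugar_metabolism
GRMZM2G152908\tsus1\t9\tsugar_metabolism
GRMZM2G175423\tsodh1\t1\tsugar_metabolism
"""

#: id of the internal-control (reference) gene conventionally used with this
#: panel: the 18S rRNA coding gene.
DEFAULT_REFERENCE_GENE = "18S"


def study_pedigree() -> list[PedigreeEntry]:
    """The five parent/hybrid trios of the reference panel."""
    df = pd.read_csv(io.StringIO(STUDY_PEDIGREE_TSV), sep="\t", dtype=str)
    return frame_to_records(df, PedigreeEntry)


def candidate_genes() -> list[GeneAnnotation]:
    """The 52 drought-responsive candidate genes of the reference panel."""
    df = pd.read_csv(io.StringIO(CANDIDATE_GENES_TSV), sep="\t", dtype=str)
    return frame_to_records(df, GeneAnnotation)


def write_study_tables(directory: str | Path) -> tuple[Path, Path]:
    """Write the built-in pedigree and annotation tables as TSV files;
    returns (pedigree_path, annotation_path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ped = directory / "pedigree.tsv"
    ann = directory / "annotation.tsv"
    ped.write_text(STUDY_PEDIGREE_TSV, encoding="utf-8")
    ann.write_text(CANDIDATE_GENES_TSV, encoding="utf-8")
    return ped, ann
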