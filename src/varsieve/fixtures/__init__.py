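"""Packaged reference tables for the speech-delay cohort analysis.

Three variant tables transcribe the study's published candidate lists:

* ``table1_plof`` — 5 rare probable loss-of-function variants in intolerant
  genes found in the 13 singleton probands;
* ``table2_missense`` — 18 rare likely-deleterious missense / in-frame
  variants in intolerant genes from the same singletons;
* ``table3_denovo`` — 6 de novo exonic variants from the 10 trios.

Published tables print genomic positions and HGVS cDNA/protein labels but
no VCF alleles: the ``ref``/``alt`` columns here are synthetic placeholder
alleles reconstructed from the cDNA notation and serve only as join keys.
``dist_to_transcript_end`` values are likewise reconstructed from protein
lengths and truncation positions. ``kaviar_af`` is set to 0 (the published
tables print the gnomAD frequency only).

``gene_evidence`` and ``variant_context`` encode the curated knowledge the
interpretation step used (prior gene–disease associations, causal-cluster
intervals, ClinVar interpretations, inheritance established by Sanger
segregation).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from ..classify import GeneEvidence, read_gene_evidence, read_variant_context
from ..io import variant_from_row
from ..model import AnnotatedVariant

__all__ = [
    "fixture_path",
    "load_variant_table",
    "load_table1_plof",
    "load_table2_missense",
    "load_table3_denovo",
    "load_gene_evidence",
    "load_variant_context",
    "ALL_PROBANDS",
    "SINGLETON_PROBANDS",
    "TRIO_PROBANDS",
]

#: The full cohort: 13 singleton probands then 10 trio probands.
SINGLETON_PROBANDS = tuple(f"{i:02d}" for i in range(1, 14))
TRIO_PROBANDS = tuple(f"{i:02d}" for i in range(14, 24))
ALL_PROBANDS = SINGLETON_PROBANDS + TRIO_PROBANDS


def fixture_path(name: str) -> Path:
    return Path(str(resources.files(__package__) / "data" / name))


def load_variant_table(name: str) -> list[tuple[str, AnnotatedVariant, str]]:
    """Rows of a fixture variant table: (proband, variant, printed tier)."""
    df = pd.read_csv(fixture_path(name), sep="\t", dtype=str)
    rows = []
    for record in df.to_dict(orient="records"):
        variant = variant_from_row(record)
        rows.append((str(record["proband"]), variant, str(record["classification"])))
    return rows


def load_table1_plof() -> list[tuple[str, AnnotatedVariant, str]]:
    return load_variant_table("table1_plof.tsv")


def load_table2_missense() -> list[tuple[str, AnnotatedVariant, str]]:
    return load_variant_table("table2_missense.tsv")


def load_table3_denovo() -> list[tuple[str, AnnotatedVariant, str]]:
    return load_variant_table("table3_denovo.tsv")


def load_gene_evidence() -> dict[str, GeneEvidence]:
    return read_gene_evidence(fixture_path("gene_evidence.tsv"))


def load_variant_context() -> dict[tuple[str, str], dict]:
    return read_variant_context(fixture_path("variant_context.tsv"))
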