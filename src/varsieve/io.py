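"""Readers and writers for the cohort input bundle.

Three files describe a cohort:

* a VCF 4.x file with per-sample ``GT`` and ``AD`` fields (the caller's
  FILTER column carries the recalibration verdict: ``PASS`` → pass),
* a tab-separated annotation table keyed by (chrom, pos, ref, alt) with the
  fixed header in :data:`ANNOTATION_COLUMNS`,
* a three-column pedigree TSV (proband, father, mother; ``.`` for an absent
  parent — singleton designs leave both parent columns as ``.``).

``read_cohort`` joins the three into ``CohortRecord`` objects; VCF records
without an annotation row are reported and dropped, duplicated annotation
keys and pedigree samples missing from the VCF are errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .model import (
    AnnotatedVariant,
    Consequence,
    FilterStatus,
    Genotype,
    GenotypeCall,
    LocalTolerance,
    PolyphenCall,
    SiftCall,
    SpliceSiteClass,
    TrioRecord,
    VariantKey,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ANNOTATION_COLUMNS",
    "CohortRecord",
    "read_pedigree",
    "write_pedigree",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
    "CohortParseError",
]

#: Fixed annotation-table header. ``.`` encodes an absent value; booleans
#: are written 1/0. ``filter_status`` is carried by the VCF FILTER column,
#: not by this table.
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
    "cdna_change", "protein_change", "gnomad_af", "kaviar_af", "pli",
    "mis_z", "local_tolerance", "sift", "polyphen", "revel", "gerp",
    "brain_expressed", "in_segdup", "dist_to_transcript_end",
    "affects_protein_domain", "splice_site_class",
]


class CohortParseError(ValueError):
    """A cohort input file violates the documented format."""


@dataclass(frozen=True)
class CohortRecord:
    """One variant joined with the cohort's per-sample genotype calls."""

    variant: AnnotatedVariant
    genotypes: Mapping[str, GenotypeCall]


# ---------------------------------------------------------------------------
# pedigree

def read_pedigree(path: str | Path) -> list[TrioRecord]:
    trios: list[TrioRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise CohortParseError(
                f"{path}:{lineno}: pedigree rows need 3 tab-separated columns"
            )
        proband, father, mother = fields
        if proband in seen:
            raise CohortParseError(f"{path}:{lineno}: duplicate proband {proband}")
        seen.add(proband)
        trios.append(
            TrioRecord(
                proband_id=proband,
                father_id=None if father == "." else father,
                mother_id=None if mother == "." else mother,
            )
        )
    return trios


def write_pedigree(trios: Iterable[TrioRecord], path: str | Path) -> None:
    lines = ["#proband\tfather\tmother"]
    for t in trios:
        lines.append(f"{t.proband_id}\t{t.father_id or '.'}\t{t.mother_id or '.'}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation table

_ENUM_FIELDS = {
    "consequence": Consequence,
    "local_tolerance": LocalTolerance,
    "sift": SiftCall,
    "polyphen": PolyphenCall,
    "splice_site_class": SpliceSiteClass,
}
_FLOAT_OPTIONAL = {"pli", "mis_z", "revel", "gerp"}
_BOOL_FIELDS = {"brain_expressed", "in_segdup", "affects_protein_domain"}


def _parse_optional_float(raw: str) -> Optional[float]:
    return None if raw in (".", "", "NA") else float(raw)


def variant_from_row(row: Mapping[str, object], *,
                     filter_status: FilterStatus = FilterStatus.pass_) -> AnnotatedVariant:
    """Build an :class:`AnnotatedVariant` from one annotation-table row."""
    kwargs: dict[str, object] = {"filter_status": filter_status}
    for col in ANNOTATION_COLUMNS:
        raw = row[col]
        raw = "." if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
        if col in _ENUM_FIELDS:
            enum_cls = _ENUM_FIELDS[col]
            if raw in (".", "", "NA"):
                if enum_cls is SiftCall or enum_cls is PolyphenCall:
                    kwargs[col] = enum_cls.unavailable
                elif enum_cls is LocalTolerance:
                    kwargs[col] = LocalTolerance.unavailable
                else:
                    raise CohortParseError(f"column {col} may not be absent")
            else:
                kwargs[col] = enum_cls(raw)
        elif col in _FLOAT_OPTIONAL:
            kwargs[col] = _parse_optional_float(raw)
        elif col in _BOOL_FIELDS:
            kwargs[col] = raw in ("1", "true", "True")
        elif col in ("gnomad_af", "kaviar_af"):
            kwargs[col] = float(raw) if raw not in (".", "") else 0.0
        elif col == "pos":
            kwargs[col] = int(raw)
        elif col == "dist_to_transcript_end":
            kwargs[col] = None if raw in (".", "", "NA") else int(float(raw))
        else:
            kwargs[col] = raw
    return AnnotatedVariant(**kwargs)  # type: ignore[arg-type]


def variant_to_row(v: AnnotatedVariant) -> dict[str, str]:
    def fmt(value: object) -> str:
        if value is None:
            return "."
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    row = {}
    for col in ANNOTATION_COLUMNS:
        value = getattr(v, col)
        if hasattr(value, "value"):
            value = value.value
        row[col] = fmt(value)
    return row


def read_annotations(path: str | Path) -> dict[VariantKey, dict[str, str]]:
    """Annotation rows keyed by (chrom, pos, ref, alt); duplicates are errors."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortParseError(f"{path}: cannot parse annotation table: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing annotation columns {missing}")
    rows: dict[VariantKey, dict[str, str]] = {}
    for i, row in enumerate(df.to_dict(orient="records"), start=2):
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        if key in rows:
            raise CohortParseError(f"{path}: line {i}: duplicate variant key {key}")
        rows[key] = row
    return rows


def write_annotations(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    df = pd.DataFrame([variant_to_row(v) for v in variants], columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def _gt_from_tuple(gt: tuple | None) -> Genotype:
    if gt is None or all(a is None for a in gt):
        return Genotype.missing
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return Genotype.hom_ref
    if all(a == 1 for a in alleles):
        return Genotype.hom_alt
    return Genotype.het


def read_cohort(
    vcf_path: str | Path,
    annotation_path: str | Path,
    pedigree_path: str | Path,
) -> tuple[list[CohortRecord], list[TrioRecord]]:
    """Join VCF genotypes, annotation rows and the pedigree.

    Returns the joined records (VCF order) and the pedigree.  Variants with
    no annotation row are logged and dropped; a pedigree sample absent from
    the VCF is an error.
    """
    annotations = read_annotations(annotation_path)
    trios = read_pedigree(pedigree_path)

    records: list[CohortRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = set(vcf.header.samples)
        for trio in trios:
            for sid in (trio.proband_id, *trio.parent_ids):
                if sid not in vcf_samples:
                    raise CohortParseError(
                        f"pedigree sample {sid!r} absent from VCF {vcf_path}"
                    )
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise CohortParseError(
                    f"{vcf_path}: record {rec.chrom}:{rec.pos} must be biallelic"
                )
            key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
            row = annotations.pop(key, None)
            if row is None:
                logger.warning("variant %s has no annotation row; dropped", key)
                continue
            filters = list(rec.filter.keys())
            status = (
                FilterStatus.pass_
                if filters in ([], ["PASS"]) or filters == ["."]
                else FilterStatus.fail
            )
            variant = variant_from_row(row, filter_status=status)
            genotypes = {}
            for sid in rec.samples:
                sample = rec.samples[sid]
                ad = sample.get("AD")
                depths = (int(ad[0] or 0), int(ad[1] or 0)) if ad is not None else (0, 0)
                genotypes[sid] = GenotypeCall(
                    sample_id=sid, gt=_gt_from_tuple(sample.get("GT")), allele_depths=depths
                )
            records.append(CohortRecord(variant=variant, genotypes=genotypes))
    if annotations:
        logger.warning(
            "%d annotation rows had no matching VCF record", len(annotations)
        )
    return records, trios


_CHROM_ORDER = [str(c) for c in range(1, 23)] + ["X", "Y", "MT"]


def write_cohort(
    records: Iterable[CohortRecord],
    trios: Iterable[TrioRecord],
    vcf_path: str | Path,
    annotation_path: str | Path,
    pedigree_path: str | Path,
) -> None:
    """Write the joined cohort back to VCF + annotation TSV + pedigree TSV.

    Round-trips with :func:`read_cohort`: re-reading the written bundle
    yields an identical collection.
    """
    records = list(records)
    trios = list(trios)
    samples: list[str] = []
    for t in trios:
        for sid in (t.proband_id, *t.parent_ids):
            if sid not in samples:
                samples.append(sid)

    header = pysam.VariantHeader()
    header.add_meta("source", "varsieve")
    chroms = sorted(
        {r.variant.chrom for r in records},
        key=lambda c: (_CHROM_ORDER.index(c) if c in _CHROM_ORDER else 99, c),
    )
    for chrom in chroms:
        header.contigs.add(chrom, length=250_000_000)
    header.filters.add("FAIL", None, None, "Recalibration failure")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    for sid in samples:
        header.add_sample(sid)

    _GT_TUPLES = {
        Genotype.hom_ref: (0, 0),
        Genotype.het: (0, 1),
        Genotype.hom_alt: (1, 1),
        Genotype.missing: (None, None),
    }
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (chroms.index(r.variant.chrom), r.variant.pos)):
            v = rec.variant
            vrec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            vrec.filter.add("PASS" if v.filter_status is FilterStatus.pass_ else "FAIL")
            for sid in samples:
                call = rec.genotypes.get(
                    sid, GenotypeCall(sample_id=sid, gt=Genotype.missing)
                )
                vrec.samples[sid]["GT"] = _GT_TUPLES[call.gt]
                vrec.samples[sid]["AD"] = call.allele_depths
            out.write(vrec)

    write_annotations((r.variant for r in records), annotation_path)
    write_pedigree(trios, pedigree_path)
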