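"""Five-tier interpretation of cascade survivors.

Surviving variants are placed into {pathogenic, likely pathogenic, VUS,
likely benign, benign} by a deterministic rule table that combines the
variant class with curated gene-level evidence (prior gene–disease
association, disease mechanism, causal-variant clusters along the protein)
and per-variant context (inheritance, population novelty, ClinVar status,
predicted nonsense-mediated decay, residue conservation, competing findings
in the same proband).  Rules fire in fixed priority order and every fired
rule is recorded as a machine-readable rationale code:

R1  ClinVar override — an existing benign/likely-benign interpretation is
    adopted; conflicting interpretations force VUS.
R2  Pathogenic — truncating variant predicted to trigger nonsense-mediated
    decay in an established haploinsufficiency gene whose phenotype is not
    dissimilar to the proband's.
R3  Likely pathogenic — missense in an established missense-mechanism
    gene, absent from population databases, at a conserved residue, with
    high predicted impact, inside a known causal cluster (or the gene's
    critical-domain flag set).
R4  VUS demotions — established gene but outside the causal cluster, or a
    dissimilar associated phenotype, or a gene with no established
    association, or inheritance from an unaffected parent, or a competing
    likely-pathogenic/pathogenic finding in the same proband.
R5  Default — VUS.

The table intentionally encodes the dispositions a strict research-cohort
analysis produces, not the full clinical ACMG/AMP criterion catalog.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cascade import FilterVerdict, PASS
from .model import AnnotatedVariant, Consequence, FilterConfig, PLOF_CONSEQUENCES

logger = logging.getLogger(__name__)

__all__ = [
    "TierValue",
    "Tier",
    "ClinVarStatus",
    "Inheritance",
    "PhenotypeSimilarity",
    "GeneEvidence",
    "VariantContext",
    "nmd_predicted",
    "in_causal_cluster",
    "classify",
    "classify_cohort",
    "cohort_report",
    "read_gene_evidence",
    "read_variant_context",
]


class TierValue(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    vus = "vus"
    likely_benign = "likely_benign"
    benign = "benign"


#: Ordering toward pathogenic, for monotonicity checks and "best finding".
TIER_SEVERITY = {
    TierValue.benign: 0,
    TierValue.likely_benign: 1,
    TierValue.vus: 2,
    TierValue.likely_pathogenic: 3,
    TierValue.pathogenic: 4,
}


@dataclass(frozen=True)
class Tier:
    value: TierValue
    rationale_codes: tuple[str, ...] = ()


class ClinVarStatus(str, enum.Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    conflicting = "conflicting"
    likely_benign = "likely_benign"
    benign = "benign"
    absent = "absent"


class Inheritance(str, enum.Enum):
    de_novo = "de_novo"
    inherited_affected_parent = "inherited_affected_parent"
    inherited_unaffected_parent = "inherited_unaffected_parent"
    unknown = "unknown"


class PhenotypeSimilarity(str, enum.Enum):
    overlapping = "overlapping"
    dissimilar = "dissimilar"
    unknown = "unknown"


@dataclass(frozen=True)
class GeneEvidence:
    """Curated prior knowledge about a gene (literature/OMIM/ClinVar-derived)."""

    gene: str
    established_ndd_gene: bool = False
    lof_mechanism: bool = False
    missense_mechanism: bool = False
    causal_cluster: tuple[tuple[int, int], ...] = ()  # amino-acid intervals
    domain_critical: bool = False
    phenotype_similarity: PhenotypeSimilarity = PhenotypeSimilarity.unknown
    notes: str = ""


@dataclass(frozen=True)
class VariantContext:
    """Per-variant interpretation context beyond the annotation table."""

    inheritance: Inheritance = Inheritance.unknown
    novel_in_population: bool = False
    clinvar: ClinVarStatus = ClinVarStatus.absent
    nmd_predicted: bool = False
    protein_position: Optional[int] = None
    conserved_residue: bool = False
    competing_lp_or_p_in_proband: bool = False


def nmd_predicted(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """Nonsense-mediated decay prediction for truncating variants.

    A stop-gain/frameshift escapes decay when it lies within the
    end-of-transcript window (``nmd_end_window_bp`` coding bp, strict);
    beyond the window the transcript is predicted to be degraded, i.e.
    haploinsufficiency.  Other consequences: not applicable (``None``).
    """
    if variant.consequence not in (Consequence.stop_gain, Consequence.frameshift):
        return None
    if variant.dist_to_transcript_end is None:
        raise ValueError(f"{variant.key}: dist_to_transcript_end required")
    return variant.dist_to_transcript_end > config.nmd_end_window_bp


def in_causal_cluster(protein_position: Optional[int], evidence: GeneEvidence) -> bool:
    """True iff the residue falls in any known causal-variant cluster interval."""
    if protein_position is None:
        return False
    return any(lo <= protein_position <= hi for lo, hi in evidence.causal_cluster)


def build_context(
    variant: AnnotatedVariant,
    config: FilterConfig,
    *,
    inheritance: Inheritance = Inheritance.unknown,
    clinvar: ClinVarStatus = ClinVarStatus.absent,
    protein_position: Optional[int] = None,
    competing_lp_or_p_in_proband: bool = False,
) -> VariantContext:
    """Derive the computable context fields from the annotation record."""
    nmd = (
        nmd_predicted(variant, config)
        if variant.consequence in (Consequence.stop_gain, Consequence.frameshift)
        else False
    )
    return VariantContext(
        inheritance=inheritance,
        novel_in_population=variant.max_db_af == 0.0,
        clinvar=clinvar,
        nmd_predicted=bool(nmd),
        protein_position=protein_position,
        conserved_residue=variant.gerp is not None and variant.gerp > config.gerp_min,
        competing_lp_or_p_in_proband=competing_lp_or_p_in_proband,
    )


_CLINVAR_TIER = {
    ClinVarStatus.likely_benign: TierValue.likely_benign,
    ClinVarStatus.benign: TierValue.benign,
}


def classify(
    variant: AnnotatedVariant,
    verdict: Optional[FilterVerdict],
    evidence: Optional[GeneEvidence],
    context: VariantContext,
) -> Tier:
    """Apply the five-tier rule table (R1 > R2 > R3 > R4 > R5 default).

    ``verdict`` supplies the cascade's missense-impact outcome for R3; a
    missing gene-evidence row yields VUS with the ``no-evidence`` code.
    """
    codes: list[str] = []
    if evidence is None:
        logger.warning("no gene-evidence row for %s; classifying as VUS", variant.gene)
        return Tier(TierValue.vus, ("no-evidence",))

    # R1: adopt existing benign-side ClinVar interpretations; conflicting -> VUS
    if context.clinvar in _CLINVAR_TIER:
        codes.append(f"R1-clinvar-{context.clinvar.value}")
        return Tier(_CLINVAR_TIER[context.clinvar], tuple(codes))
    if context.clinvar is ClinVarStatus.conflicting:
        codes.append("R1-clinvar-conflicting")
        return Tier(TierValue.vus, tuple(codes))

    # R2: pathogenic — NMD-triggering truncation in an established LoF gene
    if (
        variant.consequence in PLOF_CONSEQUENCES
        and context.nmd_predicted
        and evidence.established_ndd_gene
        and evidence.lof_mechanism
        and evidence.phenotype_similarity is not PhenotypeSimilarity.dissimilar
        and not context.competing_lp_or_p_in_proband
    ):
        codes.append("R2-pathogenic-lof")
        return Tier(TierValue.pathogenic, tuple(codes))

    # R3: likely pathogenic — clustered novel damaging missense in an
    # established missense-mechanism gene
    if (
        variant.consequence is Consequence.missense
        and evidence.established_ndd_gene
        and evidence.missense_mechanism
        and evidence.phenotype_similarity is not PhenotypeSimilarity.dissimilar
        and context.novel_in_population
        and context.conserved_residue
        and verdict is not None
        and verdict.outcome_of("impact") == PASS
        and (
            in_causal_cluster(context.protein_position, evidence)
            or (not evidence.causal_cluster and evidence.domain_critical)
        )
        and not context.competing_lp_or_p_in_proband
    ):
        codes.append("R3-likely-pathogenic-missense")
        return Tier(TierValue.likely_pathogenic, tuple(codes))

    # R4: explicit VUS demotions (recorded for the audit trail)
    if evidence.established_ndd_gene and evidence.causal_cluster and not in_causal_cluster(
        context.protein_position, evidence
    ):
        codes.append("R4-outside-causal-cluster")
    if evidence.phenotype_similarity is PhenotypeSimilarity.dissimilar:
        codes.append("R4-dissimilar-phenotype")
    if not evidence.established_ndd_gene:
        codes.append("R4-gene-not-established")
    if context.inheritance is Inheritance.inherited_unaffected_parent:
        codes.append("R4-inherited-from-unaffected-parent")
    if context.competing_lp_or_p_in_proband:
        codes.append("R4-competing-finding-in-proband")
    if codes:
        return Tier(TierValue.vus, tuple(codes))

    # R5: default
    return Tier(TierValue.vus, ("R5-default",))


@dataclass
class ClassifiedVariant:
    proband_id: str
    variant: AnnotatedVariant
    tier: Tier
    context: VariantContext


def classify_cohort(
    survivors: Sequence[tuple[str, AnnotatedVariant, Optional[FilterVerdict]]],
    evidence_by_gene: Mapping[str, GeneEvidence],
    contexts: Mapping[tuple, VariantContext],
) -> list[ClassifiedVariant]:
    """Classify all survivors, resolving competing findings per proband.

    Two passes: the first classifies every variant independently; the
    second sets ``competing_lp_or_p_in_proband`` for variants sharing a
    proband with a likely-pathogenic/pathogenic finding and reclassifies
    (demotions only — a competing finding can never raise a tier).
    """
    def run(ctx_override: Mapping[tuple, VariantContext]) -> list[ClassifiedVariant]:
        out = []
        for proband_id, variant, verdict in survivors:
            ctx = ctx_override.get((proband_id, variant.key), VariantContext())
            tier = classify(variant, verdict, evidence_by_gene.get(variant.gene), ctx)
            out.append(ClassifiedVariant(proband_id, variant, tier, ctx))
        return out

    base_contexts = {
        (pid, v.key): contexts.get((pid, v.key), VariantContext())
        for pid, v, _ in survivors
    }
    first = run(base_contexts)
    lp_probands: dict[str, set] = {}
    for cv in first:
        if cv.tier.value in (TierValue.pathogenic, TierValue.likely_pathogenic):
            lp_probands.setdefault(cv.proband_id, set()).add(cv.variant.key)
    amended = dict(base_contexts)
    for (pid, key), ctx in base_contexts.items():
        competing = lp_probands.get(pid, set()) - {key}
        if competing:
            amended[(pid, key)] = replace(ctx, competing_lp_or_p_in_proband=True)
    return run(amended)


def cohort_report(
    classified: Sequence[ClassifiedVariant], probands: Sequence[str]
) -> pd.DataFrame:
    """Per-proband best finding and the cohort diagnostic yield.

    The yield is the percentage of probands with at least one pathogenic or
    likely-pathogenic variant, rounded to the nearest integer percent; it
    is stored on every row in the ``yield_percent`` column.
    """
    best: dict[str, ClassifiedVariant] = {}
    for cv in classified:
        cur = best.get(cv.proband_id)
        if cur is None or TIER_SEVERITY[cv.tier.value] > TIER_SEVERITY[cur.tier.value]:
            best[cv.proband_id] = cv
    solved = sum(
        1
        for cv in best.values()
        if cv.tier.value in (TierValue.pathogenic, TierValue.likely_pathogenic)
    )
    yield_percent = round(100.0 * solved / len(probands)) if probands else 0
    rows = []
    for pid in probands:
        cv = best.get(pid)
        rows.append(
            {
                "proband": pid,
                "best_gene": cv.variant.gene if cv else ".",
                "best_tier": cv.tier.value.value if cv else ".",
                "rationale": ";".join(cv.tier.rationale_codes) if cv else ".",
                "solved": bool(
                    cv
                    and cv.tier.value
                    in (TierValue.pathogenic, TierValue.likely_pathogenic)
                ),
                "yield_percent": yield_percent,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evidence / context tables

GENE_EVIDENCE_COLUMNS = [
    "gene", "established_ndd_gene", "lof_mechanism", "missense_mechanism",
    "causal_cluster", "domain_critical", "phenotype_similarity", "notes",
]

VARIANT_CONTEXT_COLUMNS = [
    "gene", "proband", "inheritance", "clinvar", "protein_position",
]


def _parse_clusters(raw: str) -> tuple[tuple[int, int], ...]:
    if raw in (".", "", "NA") or pd.isna(raw):
        return ()
    out = []
    for part in str(raw).split(";"):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return tuple(out)


def read_gene_evidence(path: str | Path) -> dict[str, GeneEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(".")
    out = {}
    for row in df.to_dict(orient="records"):
        gene = str(row["gene"])
        out[gene] = GeneEvidence(
            gene=gene,
            established_ndd_gene=row["established_ndd_gene"] == "1",
            lof_mechanism=row["lof_mechanism"] == "1",
            missense_mechanism=row["missense_mechanism"] == "1",
            causal_cluster=_parse_clusters(row["causal_cluster"]),
            domain_critical=row.get("domain_critical", "0") == "1",
            phenotype_similarity=PhenotypeSimilarity(row["phenotype_similarity"]),
            notes=str(row.get("notes", "")),
        )
    return out


def read_variant_context(path: str | Path) -> dict[tuple[str, str], dict]:
    """Context rows keyed by (proband, gene): inheritance/ClinVar/position."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(".")
    out = {}
    for row in df.to_dict(orient="records"):
        key = (str(row["proband"]), str(row["gene"]))
        out[key] = {
            "inheritance": Inheritance(row["inheritance"])
            if row["inheritance"] != "." else Inheritance.unknown,
            "clinvar": ClinVarStatus(row["clinvar"])
            if row["clinvar"] != "." else ClinVarStatus.absent,
            "protein_position": None
            if row["protein_position"] in (".", "") else int(row["protein_position"]),
        }
    return out
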