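"""The rare-variant prioritization cascade.

Variants reach one of three routes depending on the sequencing design and
consequence class:

* ``trio_denovo`` — trio probands: de novo detection (present in the child,
  absent from both parents), then the frequency ceiling, brain expression,
  and a damaging-and-intolerant evaluation (pLoF in a pLI-intolerant gene,
  or a missense call that is neither predicted tolerated by the protein nor
  located in a missense-tolerant (region of a) gene);
* ``singleton_plof`` — singleton probands, truncating/splice variants:
  parental-panel absence, frequency ceiling, pLI gene intolerance, impact
  (essential splice sites only; truncations within 50 coding bp of the
  transcript end are rescued only if they hit a protein domain), brain
  expression;
* ``singleton_missense`` — singleton probands, missense and in-frame
  indels: parental-panel absence, frequency ceiling, gene intolerance
  (MIS_Z or pLI plus an intolerant regional tolerance category), predictor
  impact (GERP, REVEL, SIFT/PolyPhen; bypassed for in-frame indels, whose
  predictors are undefined), brain expression.

Every filter is a pure conjunctive predicate, so the surviving set does not
depend on the order of application; verdicts record each filter's outcome
(pass/fail/not-applicable) for auditability.

Absent annotation values are conservative by default: an absent constraint
score cannot demonstrate intolerance and an absent predictor cannot
demonstrate impact, so the corresponding clause fails.  The
``missing_scores_nonblocking`` switch inverts this for the missense gene
and impact filters (absent values become non-blocking), which is needed to
retain variants whose regional tolerance or predictor columns are not
available for the transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .io import CohortRecord
from .model import (
    INTOLERANT_CATEGORIES,
    MISSENSE_LIKE,
    PLOF_CONSEQUENCES,
    TOLERANT_CATEGORIES,
    AnnotatedVariant,
    Consequence,
    FilterConfig,
    Genotype,
    GenotypeCall,
    LocalTolerance,
    PolyphenCall,
    SiftCall,
    SpliceSiteClass,
    TrioRecord,
    VariantKey,
    qc_pass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterVerdict",
    "Route",
    "is_denovo",
    "parental_panel_filter",
    "maf_filter",
    "plof_gene_filter",
    "missense_gene_filter",
    "plof_impact_filter",
    "missense_impact_filter",
    "brain_expression_filter",
    "evaluate_denovo",
    "run_cascade",
]

PASS, FAIL, NA = "pass", "fail", "na"


class Route:
    singleton_plof = "singleton_plof"
    singleton_missense = "singleton_missense"
    trio_denovo = "trio_denovo"


@dataclass
class FilterVerdict:
    """Per-variant audit trail: one (filter, outcome) entry per filter."""

    key: VariantKey
    proband_id: str
    route: str
    outcomes: list[tuple[str, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def record(self, name: str, outcome: str) -> None:
        self.outcomes.append((name, outcome))

    @property
    def survived(self) -> bool:
        return all(outcome != FAIL for _, outcome in self.outcomes)

    def outcome_of(self, name: str) -> Optional[str]:
        for filt, outcome in self.outcomes:
            if filt == name:
                return outcome
        return None


# ---------------------------------------------------------------------------
# individual predicates

def is_denovo(
    variant: AnnotatedVariant,
    proband_gt: GenotypeCall,
    father_gt: GenotypeCall,
    mother_gt: GenotypeCall,
    *,
    require_zero_parent_alt_reads: bool = True,
) -> Optional[bool]:
    """De novo test: alt in the proband, absent from both parents.

    Both parents must be called homozygous reference and, by default,
    show zero alt-supporting reads (guards against under-called mosaic
    transmission).  Returns ``None`` (not applicable) when any of the three
    genotypes is missing.
    """
    calls = (proband_gt, father_gt, mother_gt)
    if any(c.gt is Genotype.missing for c in calls):
        return None
    if not proband_gt.carries_alt:
        return False
    for parent in (father_gt, mother_gt):
        if parent.gt is not Genotype.hom_ref:
            return False
        if require_zero_parent_alt_reads and parent.allele_depths[1] > 0:
            return False
    return True


def parental_panel_filter(
    variant: AnnotatedVariant, panel_genotypes: Mapping[str, GenotypeCall]
) -> bool:
    """True iff no parental sample in the panel carries the alt allele."""
    if not panel_genotypes:
        logger.warning("parental panel is empty; panel filter passes vacuously")
        return True
    return not any(call.carries_alt for call in panel_genotypes.values())


def maf_filter(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Strict frequency ceiling on the stricter of the two databases."""
    return variant.max_db_af < config.maf_ceiling


def plof_gene_filter(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """pLoF gene intolerance: pLI strictly above the threshold.

    Absent pLI fails (an unknown constraint score cannot demonstrate
    intolerance).  Not applicable to non-pLoF consequences.
    """
    if variant.consequence not in PLOF_CONSEQUENCES:
        return None
    return variant.pli is not None and variant.pli > config.pli_min


def missense_gene_filter(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """Missense gene intolerance: (MIS_Z or pLI) plus an intolerant locus.

    The gene must be constrained (MIS_Z > threshold or pLI > threshold)
    AND the residue must fall in a regionally intolerant category.  Absent
    scores fail their clause unless ``missing_scores_nonblocking``.
    """
    if variant.consequence not in MISSENSE_LIKE:
        return None
    nonblocking = config.missing_scores_nonblocking
    mis_z_hit = variant.mis_z is not None and variant.mis_z > config.mis_z_min
    pli_hit = variant.pli is not None and variant.pli > config.pli_min
    if variant.mis_z is None and variant.pli is None and nonblocking:
        gene_constrained = True
    else:
        gene_constrained = mis_z_hit or pli_hit
    if variant.local_tolerance is LocalTolerance.unavailable:
        locus_intolerant = nonblocking
    else:
        locus_intolerant = variant.local_tolerance in INTOLERANT_CATEGORIES
    return gene_constrained and locus_intolerant


def plof_impact_filter(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """pLoF impact by gene location.

    Splice variants must hit the main donor/acceptor sites.  Truncating
    variants within ``nmd_end_window_bp`` coding bp of the transcript end
    are excluded unless they disrupt a protein domain.
    """
    if variant.consequence not in PLOF_CONSEQUENCES:
        return None
    if variant.consequence is Consequence.splice:
        return variant.splice_site_class is SpliceSiteClass.main_donor_acceptor
    if variant.dist_to_transcript_end is None:
        raise ValueError(
            f"{variant.key}: dist_to_transcript_end required for "
            f"{variant.consequence.value} variants"
        )
    return (
        variant.dist_to_transcript_end > config.nmd_end_window_bp
        or variant.affects_protein_domain
    )


def missense_impact_filter(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """Missense impact: conservation, ensemble score, and a damaging call.

    GERP > threshold AND REVEL > threshold AND (SIFT deleterious OR
    PolyPhen probably/possibly damaging).  In-frame indels bypass this
    filter (their per-substitution predictors are undefined) and are
    flagged upstream.  Absent predictor values fail their clause unless
    ``missing_scores_nonblocking``.
    """
    if variant.consequence is not Consequence.missense:
        return None
    nonblocking = config.missing_scores_nonblocking

    def clause(present: bool, value_ok: bool) -> bool:
        return value_ok if present else nonblocking

    gerp_ok = clause(variant.gerp is not None,
                     variant.gerp is not None and variant.gerp > config.gerp_min)
    revel_ok = clause(variant.revel is not None,
                      variant.revel is not None and variant.revel > config.revel_min)
    sift_damaging = variant.sift is SiftCall.D
    polyphen_damaging = variant.polyphen in (PolyphenCall.D, PolyphenCall.P)
    if (variant.sift is SiftCall.unavailable
            and variant.polyphen is PolyphenCall.unavailable):
        call_ok = nonblocking
    else:
        call_ok = sift_damaging or polyphen_damaging
    return gerp_ok and revel_ok and call_ok


def brain_expression_filter(variant: AnnotatedVariant) -> bool:
    """Neurodevelopmental relevance: transcript expressed in (developing) brain."""
    return variant.brain_expressed


def evaluate_denovo(variant: AnnotatedVariant, config: FilterConfig) -> Optional[bool]:
    """Damaging-and-intolerant verdict for de novo candidates.

    pLoF: pLI strictly above the threshold.  Missense: not predicted
    tolerated by the protein (tolerated ⇔ SIFT tolerated OR PolyPhen benign
    OR REVEL < 0.25) and not in a missense-tolerant (region of a) gene
    (tolerant ⇔ MIS_Z < 3 AND a tolerant regional category).  Absent MIS_Z
    does not demonstrate tolerance.
    """
    if variant.consequence in PLOF_CONSEQUENCES:
        return variant.pli is not None and variant.pli > config.pli_min
    if variant.consequence in MISSENSE_LIKE:
        tolerated_by_protein = (
            variant.sift is SiftCall.T
            or variant.polyphen is PolyphenCall.T
            or (variant.revel is not None
                and variant.revel < config.denovo_revel_tolerated_max)
        )
        gene_tolerant = (
            variant.mis_z is not None
            and variant.mis_z < config.denovo_mis_z_min
            and variant.local_tolerance in TOLERANT_CATEGORIES
        )
        return not tolerated_by_protein and not gene_tolerant
    return None


# ---------------------------------------------------------------------------
# cascade driver

def _panel_genotypes(
    record: CohortRecord, trios: Iterable[TrioRecord]
) -> dict[str, GenotypeCall]:
    panel = {}
    for trio in trios:
        for pid in trio.parent_ids:
            if pid in record.genotypes:
                panel[pid] = record.genotypes[pid]
    return panel


def run_cascade(
    records: Iterable[CohortRecord],
    trios: Iterable[TrioRecord],
    config: FilterConfig | None = None,
    *,
    apply_qc: bool = True,
) -> list[FilterVerdict]:
    """Route every proband variant and apply the full conjunctive cascade.

    Each variant is evaluated once per proband that could carry it (trio
    probands through the de novo route, singletons through the pLoF or
    missense route by consequence class); a variant never receives verdicts
    from both routes for the same proband.  All applicable filters are
    always evaluated (no short-circuiting), making the verdict an order-free
    audit trail.
    """
    config = config or FilterConfig()
    trios = list(trios)
    verdicts: list[FilterVerdict] = []

    for record in records:
        variant = record.variant
        for trio in trios:
            proband_call = record.genotypes.get(trio.proband_id)
            if proband_call is None or not proband_call.carries_alt:
                continue
            if trio.design == "trio":
                verdicts.append(
                    _trio_verdict(record, trio, config, apply_qc=apply_qc)
                )
            else:
                verdict = _singleton_verdict(
                    record, trio, trios, config, apply_qc=apply_qc
                )
                if verdict is not None:
                    verdicts.append(verdict)
    return verdicts


def _qc_outcome(record: CohortRecord, trio: TrioRecord, config: FilterConfig) -> str:
    ok = qc_pass(
        record.variant, record.genotypes, trio.proband_id, config,
        parent_ids=trio.parent_ids,
    )
    return PASS if ok else FAIL


def _trio_verdict(
    record: CohortRecord, trio: TrioRecord, config: FilterConfig, *, apply_qc: bool
) -> FilterVerdict:
    variant = record.variant
    verdict = FilterVerdict(variant.key, trio.proband_id, Route.trio_denovo)
    if apply_qc:
        verdict.record("qc", _qc_outcome(record, trio, config))
    father = record.genotypes.get(trio.father_id)
    mother = record.genotypes.get(trio.mother_id)
    if father is None or mother is None:
        dn: Optional[bool] = None
    else:
        dn = is_denovo(
            variant, record.genotypes[trio.proband_id], father, mother,
            require_zero_parent_alt_reads=config.denovo_require_zero_parent_alt_reads,
        )
    if dn is None:
        verdict.record("denovo", NA)
        verdict.flags.append("genotype missing: excluded from de novo route")
        verdict.record("route_applicable", FAIL)
        return verdict
    verdict.record("denovo", PASS if dn else FAIL)
    verdict.record("maf", PASS if maf_filter(variant, config) else FAIL)
    verdict.record(
        "brain_expression", PASS if brain_expression_filter(variant) else FAIL
    )
    damaging = evaluate_denovo(variant, config)
    if damaging is None:
        verdict.record("denovo_damaging", NA)
        verdict.record("route_applicable", FAIL)
    else:
        verdict.record("denovo_damaging", PASS if damaging else FAIL)
    return verdict


def _singleton_verdict(
    record: CohortRecord,
    trio: TrioRecord,
    trios: list[TrioRecord],
    config: FilterConfig,
    *,
    apply_qc: bool,
) -> Optional[FilterVerdict]:
    variant = record.variant
    if variant.consequence in PLOF_CONSEQUENCES:
        route = Route.singleton_plof
    elif variant.consequence in MISSENSE_LIKE:
        route = Route.singleton_missense
    else:
        logger.debug("variant %s: consequence %s outside singleton routes",
                     variant.key, variant.consequence.value)
        verdict = FilterVerdict(variant.key, trio.proband_id, Route.singleton_missense)
        verdict.record("route_applicable", NA)
        verdict.record("consequence_class", FAIL)
        return verdict

    verdict = FilterVerdict(variant.key, trio.proband_id, route)
    if apply_qc:
        verdict.record("qc", _qc_outcome(record, trio, config))
    panel = _panel_genotypes(record, trios)
    verdict.record(
        "parental_panel", PASS if parental_panel_filter(variant, panel) else FAIL
    )
    verdict.record("maf", PASS if maf_filter(variant, config) else FAIL)
    if route == Route.singleton_plof:
        gene = plof_gene_filter(variant, config)
        impact = plof_impact_filter(variant, config)
        verdict.record("gene_intolerance", PASS if gene else FAIL)
        verdict.record("impact", PASS if impact else FAIL)
    else:
        gene = missense_gene_filter(variant, config)
        verdict.record("gene_intolerance", PASS if gene else FAIL)
        if variant.consequence is Consequence.inframe_indel:
            verdict.record("impact", NA)
            verdict.flags.append("predictors unavailable")
        else:
            impact = missense_impact_filter(variant, config)
            verdict.record("impact", PASS if impact else FAIL)
    verdict.record(
        "brain_expression", PASS if brain_expression_filter(variant) else FAIL
    )
    return verdict
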