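"""Replay of the published candidate-variant tables through the pipeline.

The packaged fixture tables are post-QC, post-panel variant lists (the raw
cohort genomes are access-restricted), so replay exercises the annotation-
level cascade — frequency ceiling, gene intolerance, impact, brain
expression, the de novo evaluation rule — and the five-tier classifier,
then compares every computed disposition with the printed one.

Headline expectations: 5 surviving pLoF singletons, 18 surviving missense/
in-frame singletons (with absent regional-tolerance/predictor scores
treated as non-blocking), exactly 1 damaging-and-intolerant de novo
variant, 2 likely-pathogenic missense variants, and a 13% diagnostic yield
over 23 probands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .cascade import (
    FAIL,
    NA,
    PASS,
    FilterVerdict,
    Route,
    brain_expression_filter,
    evaluate_denovo,
    maf_filter,
    missense_gene_filter,
    missense_impact_filter,
    plof_gene_filter,
    plof_impact_filter,
)
from .classify import (
    ClinVarStatus,
    Inheritance,
    TierValue,
    build_context,
    classify_cohort,
    cohort_report,
)
from .model import AnnotatedVariant, Consequence, FilterConfig, PLOF_CONSEQUENCES
from . import fixtures

__all__ = ["annotation_verdict", "ReplayReport", "replay_published_tables"]

_TIER_LABEL = {
    TierValue.pathogenic: "Pathogenic",
    TierValue.likely_pathogenic: "Likely pathogenic",
    TierValue.vus: "VUS",
    TierValue.likely_benign: "Likely benign",
    TierValue.benign: "Benign",
}


def annotation_verdict(
    proband: str, variant: AnnotatedVariant, config: FilterConfig
) -> FilterVerdict:
    """Annotation-level cascade verdict for one pre-QC'd singleton variant."""
    if variant.consequence in PLOF_CONSEQUENCES:
        route = Route.singleton_plof
        gene = plof_gene_filter(variant, config)
        impact: Optional[bool] = plof_impact_filter(variant, config)
    else:
        route = Route.singleton_missense
        gene = missense_gene_filter(variant, config)
        impact = (
            None
            if variant.consequence is Consequence.inframe_indel
            else missense_impact_filter(variant, config)
        )
    verdict = FilterVerdict(variant.key, proband, route)
    verdict.record("maf", PASS if maf_filter(variant, config) else FAIL)
    verdict.record("gene_intolerance", PASS if gene else FAIL)
    if impact is None:
        verdict.record("impact", NA)
        verdict.flags.append("predictors unavailable")
    else:
        verdict.record("impact", PASS if impact else FAIL)
    verdict.record(
        "brain_expression", PASS if brain_expression_filter(variant) else FAIL
    )
    return verdict


@dataclass
class ReplayReport:
    plof_survivors: int = 0
    missense_survivors: int = 0
    denovo_damaging: int = 0
    denovo_damaging_genes: list[str] = field(default_factory=list)
    likely_pathogenic_missense: int = 0
    pathogenic: int = 0
    yield_percent: float = 0.0
    rows: list[dict] = field(default_factory=list)
    mismatches: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def _printed_matches(printed: str, computed_label: str) -> bool:
    options = [p.strip().rstrip("*").strip().lower() for p in printed.split("/")]
    return computed_label.lower() in options


def replay_published_tables(config: FilterConfig | None = None) -> ReplayReport:
    """Run the packaged tables through cascade + classifier and compare.

    Table 2 is replayed with ``missing_scores_nonblocking`` enabled — the
    published list retains variants whose regional tolerance or predictor
    columns are unavailable — while Table 1 uses the strict defaults.
    """
    config = config or FilterConfig()
    lenient = replace(config, missing_scores_nonblocking=True)
    report = ReplayReport()

    table1 = fixtures.load_table1_plof()
    table2 = fixtures.load_table2_missense()
    table3 = fixtures.load_table3_denovo()
    evidence = fixtures.load_gene_evidence()
    contexts_raw = fixtures.load_variant_context()

    survivors: list[tuple[str, AnnotatedVariant, FilterVerdict]] = []
    for proband, variant, printed in table1:
        verdict = annotation_verdict(proband, variant, config)
        if verdict.survived:
            report.plof_survivors += 1
            survivors.append((proband, variant, verdict))
    for proband, variant, printed in table2:
        verdict = annotation_verdict(proband, variant, lenient)
        if verdict.survived:
            report.missense_survivors += 1
            survivors.append((proband, variant, verdict))

    denovo_rows: list[tuple[str, AnnotatedVariant, FilterVerdict]] = []
    for proband, variant, printed in table3:
        damaging = evaluate_denovo(variant, config)
        if damaging:
            report.denovo_damaging += 1
            report.denovo_damaging_genes.append(variant.gene)
        denovo_rows.append((proband, variant, annotation_verdict(proband, variant, lenient)))

    contexts = {}
    for proband, variant, verdict in survivors + denovo_rows:
        raw = contexts_raw.get((proband, variant.gene), {})
        contexts[(proband, variant.key)] = build_context(
            variant,
            config,
            inheritance=raw.get("inheritance", Inheritance.unknown),
            clinvar=raw.get("clinvar", ClinVarStatus.absent),
            protein_position=raw.get("protein_position"),
        )
    classified = classify_cohort(survivors + denovo_rows, evidence, contexts)

    printed_by_key = {
        (proband, variant.key): printed
        for proband, variant, printed in table1 + table2 + table3
    }
    for cv in classified:
        printed = printed_by_key[(cv.proband_id, cv.variant.key)]
        label = _TIER_LABEL[cv.tier.value]
        row = {
            "proband": cv.proband_id,
            "gene": cv.variant.gene,
            "computed": label,
            "printed": printed,
            "rationale": ";".join(cv.tier.rationale_codes),
        }
        report.rows.append(row)
        if not _printed_matches(printed, label):
            report.mismatches.append(row)
        if cv.tier.value is TierValue.likely_pathogenic and (
            cv.variant.consequence is Consequence.missense
        ):
            report.likely_pathogenic_missense += 1
        if cv.tier.value is TierValue.pathogenic:
            report.pathogenic += 1

    summary = cohort_report(classified, list(fixtures.ALL_PROBANDS))
    report.yield_percent = float(summary["yield_percent"].iloc[0])

    expected_counts = {
        "plof_survivors": (report.plof_survivors, 5),
        "missense_survivors": (report.missense_survivors, 18),
        "denovo_damaging": (report.denovo_damaging, 1),
        "likely_pathogenic_missense": (report.likely_pathogenic_missense, 2),
        "yield_percent": (report.yield_percent, 13),
    }
    for name, (got, want) in expected_counts.items():
        if got != want:
            report.mismatches.append(
                {"headline": name, "computed": got, "printed": want}
            )
    return report
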