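"""Five-tier rule engine: NMD, clusters, rule priorities, cohort yield."""

from __future__ import annotations

import itertools

import pytest

from varsieve.cascade import FilterVerdict, PASS, Route
from varsieve.classify import (
    ClassifiedVariant,
    ClinVarStatus,
    GeneEvidence,
    Inheritance,
    PhenotypeSimilarity,
    Tier,
    TierValue,
    VariantContext,
    build_context,
    classify,
    classify_cohort,
    cohort_report,
    in_causal_cluster,
    nmd_predicted,
)
from varsieve.model import Consequence

from conftest import make_variant


def verdict_with_impact(variant, outcome=PASS):
    v = FilterVerdict(variant.key, "p1", Route.singleton_missense)
    v.record("impact", outcome)
    return v


class TestNMDPrediction:
    def test_truncation_far_from_end_triggers_decay(self, config):
        v = make_variant(consequence=Consequence.frameshift,
                         dist_to_transcript_end=1182)
        assert nmd_predicted(v, config)

    def test_truncation_near_end_escapes(self, config):
        v = make_variant(consequence=Consequence.frameshift,
                         dist_to_transcript_end=10)
        assert not nmd_predicted(v, config)

    def test_boundary_is_strict(self, config):
        v = make_variant(consequence=Consequence.frameshift,
                         dist_to_transcript_end=50)
        assert not nmd_predicted(v, config)

    def test_missense_not_applicable(self, config):
        assert nmd_predicted(make_variant(), config) is None


class TestCausalCluster:
    def test_inside_cluster(self):
        ev = GeneEvidence("SPTBN1", causal_cluster=((173, 276),))
        assert in_causal_cluster(230, ev)

    def test_outside_cluster(self):
        ev = GeneEvidence("NAA15", causal_cluster=((450, 484),))
        assert not in_causal_cluster(540, ev)

    def test_empty_cluster_list(self):
        assert not in_causal_cluster(100, GeneEvidence("G"))

    def test_inclusive_bounds(self):
        ev = GeneEvidence("G", causal_cluster=((10, 20),))
        assert in_causal_cluster(10, ev) and in_causal_cluster(20, ev)


ESTABLISHED_LOF = GeneEvidence("G", True, True, False, (), False,
                               PhenotypeSimilarity.overlapping)
ESTABLISHED_MIS = GeneEvidence("G", True, False, True, ((100, 200),), False,
                               PhenotypeSimilarity.overlapping)
UNKNOWN_GENE = GeneEvidence("G")


class TestClassifyRules:
    def test_pathogenic_nmd_truncation_in_established_gene(self, config):
        # haploinsufficiency pattern, even when inherited from affected parent
        v = make_variant(consequence=Consequence.frameshift,
                         dist_to_transcript_end=1182, gene="G")
        ctx = build_context(v, config,
                            inheritance=Inheritance.inherited_affected_parent)
        tier = classify(v, None, ESTABLISHED_LOF, ctx)
        assert tier.value is TierValue.pathogenic

    def test_nmd_escape_not_pathogenic(self, config):
        v = make_variant(consequence=Consequence.frameshift,
                         dist_to_transcript_end=30,
                         affects_protein_domain=True, gene="G")
        tier = classify(v, None, ESTABLISHED_LOF, build_context(v, config))
        assert tier.value is TierValue.vus

    def test_likely_pathogenic_clustered_novel_missense(self, config):
        v = make_variant(gene="G")
        ctx = build_context(v, config, protein_position=150)
        tier = classify(v, verdict_with_impact(v), ESTABLISHED_MIS, ctx)
        assert tier.value is TierValue.likely_pathogenic

    def test_outside_cluster_demotes_to_vus(self, config):
        v = make_variant(gene="G")
        ctx = build_context(v, config, protein_position=540)
        tier = classify(v, verdict_with_impact(v), ESTABLISHED_MIS, ctx)
        assert tier.value is TierValue.vus
        assert "R4-outside-causal-cluster" in tier.rationale_codes

    def test_non_novel_variant_not_likely_pathogenic(self, config):
        v = make_variant(gene="G", gnomad_af=8e-6)
        ctx = build_context(v, config, protein_position=150)
        assert classify(v, verdict_with_impact(v), ESTABLISHED_MIS,
                        ctx).value is TierValue.vus

    def test_clinvar_override_precedes_missense_rule(self, config):
        # conflicting interpretations force VUS even for a strong candidate
        v = make_variant(gene="G")
        ctx = build_context(v, config, protein_position=150,
                            clinvar=ClinVarStatus.conflicting)
        tier = classify(v, verdict_with_impact(v), ESTABLISHED_MIS, ctx)
        assert tier.value is TierValue.vus
        assert "R1-clinvar-conflicting" in tier.rationale_codes

    def test_clinvar_likely_benign_adopted(self, config):
        v = make_variant(gene="G")
        ctx = build_context(v, config, clinvar=ClinVarStatus.likely_benign)
        assert classify(v, None, ESTABLISHED_MIS, ctx).value is TierValue.likely_benign

    def test_unestablished_gene_is_vus(self, config):
        v = make_variant(consequence=Consequence.stop_gain,
                         dist_to_transcript_end=500, gene="G")
        tier = classify(v, None, UNKNOWN_GENE, build_context(v, config))
        assert tier.value is TierValue.vus
        assert "R4-gene-not-established" in tier.rationale_codes

    def test_missing_evidence_row(self, config):
        v = make_variant()
        tier = classify(v, None, None, build_context(v, config))
        assert tier == Tier(TierValue.vus, ("no-evidence",))

    def test_totality_over_enum_space(self, config):
        """Every evidence/context combination yields exactly one tier."""
        v = make_variant(gene="G")
        positions = [None, 150, 540]
        count = 0
        for established, lof, mis, similarity, clinvar, inheritance, competing in \
                itertools.product(
                    [True, False], [True, False], [True, False],
                    PhenotypeSimilarity, ClinVarStatus, Inheritance,
                    [True, False]):
            ev = GeneEvidence("G", established, lof, mis, ((100, 200),), False,
                              similarity)
            for pos in positions:
                ctx = VariantContext(
                    inheritance=inheritance, novel_in_population=True,
                    clinvar=clinvar, protein_position=pos,
                    conserved_residue=True,
                    competing_lp_or_p_in_proband=competing,
                )
                tier = classify(v, verdict_with_impact(v), ev, ctx)
                assert isinstance(tier.value, TierValue)
                assert tier.rationale_codes
                count += 1
        assert count == 2 * 2 * 2 * 3 * 6 * 4 * 2 * 3

    def test_evidence_monotonicity(self, config):
        """Withdrawing the gene-disease association never raises the tier."""
        from varsieve.classify import TIER_SEVERITY
        import dataclasses

        v = make_variant(gene="G")
        for clinvar in ClinVarStatus:
            for pos in (None, 150, 540):
                ctx = build_context(v, config, protein_position=pos,
                                    clinvar=clinvar)
                with_assoc = classify(v, verdict_with_impact(v), ESTABLISHED_MIS, ctx)
                without = classify(
                    v, verdict_with_impact(v),
                    dataclasses.replace(ESTABLISHED_MIS, established_ndd_gene=False),
                    ctx,
                )
                assert (TIER_SEVERITY[without.value]
                        <= TIER_SEVERITY[with_assoc.value])


class TestCompetingFindings:
    def test_lp_finding_demotes_sibling_plof(self, config):
        """A strong missense in the proband demotes a co-occurring pLoF."""
        strong = make_variant(gene="G", pos=100)
        weak = make_variant(consequence=Consequence.splice, gene="W", pos=200,
                            pli=1.0)
        evidence = {"G": ESTABLISHED_MIS, "W": GeneEvidence("W")}
        contexts = {
            ("p1", strong.key): build_context(strong, config, protein_position=150),
            ("p1", weak.key): build_context(weak, config),
        }
        classified = classify_cohort(
            [("p1", strong, verdict_with_impact(strong)),
             ("p1", weak, None)],
            evidence, contexts,
        )
        by_gene = {cv.variant.gene: cv for cv in classified}
        assert by_gene["G"].tier.value is TierValue.likely_pathogenic
        assert by_gene["W"].tier.value is TierValue.vus
        assert "R4-competing-finding-in-proband" in by_gene["W"].tier.rationale_codes


class TestCohortReport:
    def _classified(self, proband, tier_value, gene="G", pos=100):
        v = make_variant(gene=gene, pos=pos)
        return ClassifiedVariant(proband, v, Tier(tier_value), VariantContext())

    @pytest.mark.parametrize(
        "n_solved,total,expected",
        [(3, 23, 13), (0, 23, 0), (23, 23, 100)],
    )
    def test_yield_percentage(self, n_solved, total, expected):
        probands = [f"p{i:02d}" for i in range(total)]
        classified = [
            self._classified(probands[i], TierValue.pathogenic, pos=100 + i)
            for i in range(n_solved)
        ]
        report = cohort_report(classified, probands)
        assert report["yield_percent"].iloc[0] == expected

    def test_best_finding_per_proband(self):
        classified = [
            self._classified("p1", TierValue.vus, gene="A", pos=1000),
            self._classified("p1", TierValue.likely_pathogenic, gene="B", pos=2000),
        ]
        report = cohort_report(classified, ["p1"])
        assert report.loc[0, "best_gene"] == "B"
        assert bool(report.loc[0, "solved"])
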