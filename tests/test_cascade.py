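"""Filter cascade: per-filter behaviour, routing, order invariance, oracles."""

from __future__ import annotations

import itertools
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from varsieve.cascade import (
    FAIL,
    Route,
    brain_expression_filter,
    evaluate_denovo,
    is_denovo,
    maf_filter,
    missense_gene_filter,
    missense_impact_filter,
    parental_panel_filter,
    plof_gene_filter,
    plof_impact_filter,
    run_cascade,
)
from varsieve.io import CohortRecord
from varsieve.model import (
    Consequence,
    FilterConfig,
    Genotype,
    GenotypeCall,
    LocalTolerance,
    PolyphenCall,
    SiftCall,
    SpliceSiteClass,
)
from varsieve.simulate import CohortConfig, generate

from conftest import het, hom_ref, make_variant


class TestDeNovoDetection:
    def test_het_child_clean_parents(self):
        assert is_denovo(make_variant(), het("kid"), hom_ref("dad"), hom_ref("mum"))

    def test_carrier_parent_blocks(self):
        assert not is_denovo(make_variant(), het("kid"), het("dad"), hom_ref("mum"))

    def test_parental_alt_reads_block_by_default(self):
        # hom_ref father with 2 stray alt reads: possible under-called mosaic
        father = hom_ref("dad", depth=30, alt_reads=2)
        assert not is_denovo(make_variant(), het("kid"), father, hom_ref("mum"))
        assert is_denovo(make_variant(), het("kid"), father, hom_ref("mum"),
                         require_zero_parent_alt_reads=False)

    def test_missing_genotype_is_not_applicable(self):
        missing = GenotypeCall("mum", Genotype.missing)
        assert is_denovo(make_variant(), het("kid"), hom_ref("dad"), missing) is None

    def test_planted_denovo_events_recovered_exactly(self):
        # five planted de novo events among thousands of transmitted variants
        from varsieve.simulate import PlantSpec

        plants = tuple(
            PlantSpec("denovo_damaging", f"tr{i:02d}", True, "vus")
            for i in range(1, 6)
        )
        cohort = generate(CohortConfig(
            n_trios=5, n_singletons=0, variants_per_proband=600,
            denovo_rate=0.0, plants=plants, seed=11,
        ))
        denovo_keys = {
            (trio.proband_id, rec.variant.key)
            for trio in cohort.trios
            for rec in cohort.records
            if rec.genotypes[trio.proband_id].carries_alt
            and is_denovo(rec.variant, rec.genotypes[trio.proband_id],
                          rec.genotypes[trio.father_id],
                          rec.genotypes[trio.mother_id])
        }
        planted = {
            (row["proband"], (str(row["chrom"]), int(row["pos"]),
                              str(row["ref"]), str(row["alt"])))
            for row in cohort.truth.to_dict(orient="records")
        }
        assert denovo_keys == planted
        assert len(planted) == 5

    def test_mendelian_violations_only_at_planted_denovo(self):
        cohort = generate(CohortConfig(
            n_trios=2, n_singletons=0, variants_per_proband=300,
            denovo_rate=1.2, plants=(), seed=13,
        ))
        for trio in cohort.trios:
            for rec in cohort.records:
                child = rec.genotypes[trio.proband_id]
                if not child.carries_alt:
                    continue
                parents_carry = any(
                    rec.genotypes[p].carries_alt for p in trio.parent_ids
                )
                dn = is_denovo(rec.variant, child, rec.genotypes[trio.father_id],
                               rec.genotypes[trio.mother_id])
                assert parents_carry != bool(dn)


class TestPanelFilter:
    def test_any_panel_carrier_excludes(self):
        panel = {"f1": hom_ref("f1"), "f2": het("f2")}
        assert not parental_panel_filter(make_variant(), panel)

    def test_absent_from_panel_passes(self):
        panel = {f"p{i}": hom_ref(f"p{i}") for i in range(20)}
        assert parental_panel_filter(make_variant(), panel)

    def test_empty_panel_passes_vacuously(self):
        assert parental_panel_filter(make_variant(), {})

    @given(st.lists(st.sampled_from(["hom_ref", "het", "hom_alt"]),
                    min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_equals_any_carrier_oracle(self, gts):
        panel = {}
        for i, name in enumerate(gts):
            gt = Genotype[name]
            panel[f"p{i}"] = GenotypeCall(f"p{i}", gt, (10, 10))
        oracle = not any(g in ("het", "hom_alt") for g in gts)
        assert parental_panel_filter(make_variant(), panel) is oracle


class TestMafFilter:
    @pytest.mark.parametrize(
        "gnomad,kaviar,expected",
        [
            (2.2e-5, 0.0, True),        # retained splice variant's frequency
            (0.0, 0.0, True),
            (3.22001e-4, 0.0, False),   # strictly above the ceiling
            (1e-5, 4e-4, False),        # the stricter database decides
        ],
    )
    def test_ceiling(self, config, gnomad, kaviar, expected):
        v = make_variant(gnomad_af=gnomad, kaviar_af=kaviar)
        assert maf_filter(v, config) is expected


class TestGeneFilters:
    def test_plof_gene(self, config):
        plof = dict(consequence=Consequence.stop_gain, dist_to_transcript_end=500)
        assert plof_gene_filter(make_variant(pli=0.95, **plof), config)
        assert not plof_gene_filter(make_variant(pli=0.90, **plof), config)  # strict
        assert not plof_gene_filter(make_variant(pli=None, **plof), config)
        assert plof_gene_filter(make_variant(), config) is None  # missense: n/a

    @pytest.mark.parametrize(
        "mis_z,pli,tol,expected",
        [
            (1.14, 1.00, LocalTolerance.intolerant, True),          # pLI rescues
            (3.01, 0.62, LocalTolerance.highly_intolerant, True),   # MIS_Z rescues
            (2.0, 0.5, LocalTolerance.intolerant, False),           # neither
            (3.0, 0.95, LocalTolerance.neutral, False),             # region tolerant
            (3.0, 0.95, LocalTolerance.slightly_intolerant, True),
        ],
    )
    def test_missense_gene(self, config, mis_z, pli, tol, expected):
        v = make_variant(mis_z=mis_z, pli=pli, local_tolerance=tol)
        assert missense_gene_filter(v, config) is expected

    def test_missing_local_tolerance_switch(self):
        v = make_variant(pli=1.0, mis_z=1.5,
                         local_tolerance=LocalTolerance.unavailable)
        assert not missense_gene_filter(v, FilterConfig())
        assert missense_gene_filter(
            v, FilterConfig(missing_scores_nonblocking=True)
        )


class TestImpactFilters:
    def test_truncation_near_transcript_end(self, config):
        near = make_variant(consequence=Consequence.frameshift,
                            dist_to_transcript_end=30)
        assert not plof_impact_filter(near, config)
        rescued = make_variant(consequence=Consequence.frameshift,
                               dist_to_transcript_end=30,
                               affects_protein_domain=True)
        assert plof_impact_filter(rescued, config)
        boundary = make_variant(consequence=Consequence.frameshift,
                                dist_to_transcript_end=50)
        assert not plof_impact_filter(boundary, config)  # strict inequality

    def test_splice_site_restriction(self, config):
        main = make_variant(consequence=Consequence.splice)
        assert plof_impact_filter(main, config)
        minor = make_variant(consequence=Consequence.splice,
                             splice_site_class=SpliceSiteClass.other)
        assert not plof_impact_filter(minor, config)

    def test_missing_distance_is_error(self, config):
        v = make_variant(consequence=Consequence.stop_gain)
        with pytest.raises(ValueError):
            plof_impact_filter(v, config)

    @pytest.mark.parametrize(
        "gerp,revel,sift,polyphen,expected",
        [
            (5.6, 0.86, SiftCall.D, PolyphenCall.D, True),
            (5.7, 0.95, SiftCall.D, PolyphenCall.D, True),
            (4.0, 0.3, SiftCall.D, PolyphenCall.D, False),   # REVEL too low
            (1.0, 0.9, SiftCall.D, PolyphenCall.D, False),   # weak conservation
            (4.0, 0.9, SiftCall.T, PolyphenCall.T, False),   # both benign calls
            (4.0, 0.9, SiftCall.T, PolyphenCall.P, True),    # possibly damaging
        ],
    )
    def test_missense_impact(self, config, gerp, revel, sift, polyphen, expected):
        v = make_variant(gerp=gerp, revel=revel, sift=sift, polyphen=polyphen)
        assert missense_impact_filter(v, config) is expected

    def test_absent_predictors_fail_by_default(self):
        v = make_variant(sift=SiftCall.unavailable,
                         polyphen=PolyphenCall.unavailable, revel=None)
        assert not missense_impact_filter(v, FilterConfig())
        assert missense_impact_filter(
            v, FilterConfig(missing_scores_nonblocking=True)
        )

    def test_brain_expression(self):
        assert brain_expression_filter(make_variant(brain_expressed=True))
        assert not brain_expression_filter(make_variant(brain_expressed=False))


class TestDeNovoEvaluation:
    def test_intolerant_stop_gain_is_damaging(self, config):
        v = make_variant(consequence=Consequence.stop_gain, pli=1.0,
                         dist_to_transcript_end=500)
        assert evaluate_denovo(v, config)

    def test_tolerated_calls_block(self, config):
        v = make_variant(sift=SiftCall.T, polyphen=PolyphenCall.T, revel=0.77)
        assert not evaluate_denovo(v, config)

    def test_tolerant_gene_region_blocks(self, config):
        v = make_variant(sift=SiftCall.D, polyphen=PolyphenCall.P, revel=0.44,
                         mis_z=1.1, pli=None,
                         local_tolerance=LocalTolerance.slightly_tolerant)
        assert not evaluate_denovo(v, config)

    def test_low_revel_counts_as_tolerated(self, config):
        v = make_variant(revel=0.17, mis_z=0.9, pli=None,
                         local_tolerance=LocalTolerance.slightly_tolerant)
        assert not evaluate_denovo(v, config)

    def test_damaging_intolerant_missense_survives(self, config):
        v = make_variant(revel=0.9, mis_z=3.5)
        assert evaluate_denovo(v, config)


def _brute_force_survivor_keys(cohort, config):
    """Independent conjunction-of-predicates evaluation (no cascade driver)."""
    keys = set()
    for rec in cohort.records:
        v = rec.variant
        for trio in cohort.trios:
            child = rec.genotypes.get(trio.proband_id)
            if child is None or not child.carries_alt:
                continue
            from varsieve.model import qc_pass as qc

            if not qc(v, rec.genotypes, trio.proband_id, config,
                      parent_ids=trio.parent_ids):
                continue
            if not (maf_filter(v, config) and brain_expression_filter(v)):
                continue
            if trio.design == "trio":
                dn = is_denovo(v, child, rec.genotypes[trio.father_id],
                               rec.genotypes[trio.mother_id])
                if dn and evaluate_denovo(v, config):
                    keys.add((trio.proband_id, v.key))
            else:
                panel = {
                    pid: rec.genotypes[pid]
                    for t in cohort.trios for pid in t.parent_ids
                    if pid in rec.genotypes
                }
                if not parental_panel_filter(v, panel):
                    continue
                if v.consequence in (Consequence.stop_gain, Consequence.frameshift,
                                     Consequence.splice):
                    if plof_gene_filter(v, config) and plof_impact_filter(v, config):
                        keys.add((trio.proband_id, v.key))
                elif v.consequence is Consequence.missense:
                    if missense_gene_filter(v, config) and missense_impact_filter(v, config):
                        keys.add((trio.proband_id, v.key))
                elif v.consequence is Consequence.inframe_indel:
                    if missense_gene_filter(v, config):
                        keys.add((trio.proband_id, v.key))
    return keys


@pytest.fixture(scope="module")
def cohort():
    return generate(CohortConfig(n_trios=3, n_singletons=4,
                                 variants_per_proband=120, seed=23,
                                 plants=()))


class TestCascadeDriver:
    def test_matches_brute_force_oracle(self, cohort, config):
        verdicts = run_cascade(cohort.records, cohort.trios, config)
        survivors = {(v.proband_id, v.key) for v in verdicts if v.survived}
        assert survivors == _brute_force_survivor_keys(cohort, config)

    def test_route_exclusivity(self, cohort, config):
        verdicts = run_cascade(cohort.records, cohort.trios, config)
        seen: dict[tuple, str] = {}
        for v in verdicts:
            assert seen.setdefault((v.proband_id, v.key), v.route) == v.route
        trio_ids = {t.proband_id for t in cohort.trios if t.design == "trio"}
        for v in verdicts:
            expected = Route.trio_denovo if v.proband_id in trio_ids else (
                Route.singleton_plof, Route.singleton_missense)
            if isinstance(expected, tuple):
                assert v.route in expected
            else:
                assert v.route == expected

    def test_order_invariance(self, config):
        """Permuting filter evaluation order never changes survival."""
        cohort = generate(CohortConfig(n_trios=0, n_singletons=2,
                                       variants_per_proband=40, seed=29,
                                       plants=()))
        verdicts = run_cascade(cohort.records, cohort.trios, config)
        for v in verdicts:
            outcomes = [o for _, o in v.outcomes]
            for perm in itertools.islice(itertools.permutations(outcomes), 24):
                assert all(o != FAIL for o in perm) == v.survived

    def test_threshold_monotonicity(self, config):
        from varsieve.simulate import PlantSpec

        plants = (
            PlantSpec("pathogenic_plof", "si01", True, "pathogenic"),
            PlantSpec("likely_pathogenic_missense", "si02", True,
                      "likely_pathogenic"),
            PlantSpec("denovo_damaging", "tr01", True, "vus"),
        )
        cohort = generate(CohortConfig(n_trios=2, n_singletons=3,
                                       variants_per_proband=100, seed=31,
                                       plants=plants))
        base = {
            (v.proband_id, v.key)
            for v in run_cascade(cohort.records, cohort.trios, config)
            if v.survived
        }
        tighter = [
            replace(config, maf_ceiling=config.maf_ceiling / 10),
            replace(config, pli_min=0.99),
            replace(config, mis_z_min=4.0),
            replace(config, gerp_min=4.9),
            replace(config, revel_min=0.85),
        ]
        for strict in tighter:
            survivors = {
                (v.proband_id, v.key)
                for v in run_cascade(cohort.records, cohort.trios, strict)
                if v.survived
            }
            assert survivors <= base

    def test_unknown_consequence_excluded_with_na(self, config, singleton):
        v = make_variant(consequence=Consequence.synonymous)
        rec = CohortRecord(variant=v, genotypes={"solo": het("solo")})
        verdicts = run_cascade([rec], [singleton], config)
        assert len(verdicts) == 1 and not verdicts[0].survived
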