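"""Seeded synthetic trio/singleton cohorts with planted causal variants.

The generator emulates the data shapes the analysis consumes — jointly
called genotypes with allele depths, an annotation table, pedigree, SV call
sets from two pseudo-callers, gene evidence, and a ground-truth manifest —
so every pipeline stage is testable without access-restricted genomes.

Statistical structure:

* 10 trios and 13 singletons by default (the study's cohort composition);
* read depths Poisson around a mean of 33 (the study's mean coverage),
  het alt fractions binomial at 0.5;
* Mendelian transmission for trio background variants (each proband-carried
  allele is present in exactly one het parent) except de novo events,
  which occur at a Poisson background rate per trio proband;
* population allele frequencies drawn from a four-component mixture
  (common / low-frequency / rare / absent-from-database);
* background annotation scores drawn from tolerant-gene, benign-score
  distributions, so that by construction no background variant survives the
  cascade — survival is decided entirely by the planted templates;
* dual-caller SV call sets with breakpoint jitter inside (and, when
  requested, outside) the concordance tolerances.

Planted templates mirror the archetypes of the study's candidate tables:
an NMD-triggering frameshift in an established haploinsufficiency gene
(pathogenic), a clustered novel damaging missense (likely pathogenic),
pLoF/missense in unestablished genes (VUS), a common benign variant
(filtered), an NMD-escaping truncation (survives, VUS), a damaging de novo
stop-gain (trio route), and a truncation inherited from an unaffected
parent (VUS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import FilterVerdict, run_cascade
from .classify import (
    ClassifiedVariant,
    GeneEvidence,
    Inheritance,
    PhenotypeSimilarity,
    VariantContext,
    build_context,
    classify_cohort,
)
from .io import CohortRecord, write_cohort
from .model import (
    AnnotatedVariant,
    Consequence,
    FilterConfig,
    FilterStatus,
    Genotype,
    GenotypeCall,
    LocalTolerance,
    PolyphenCall,
    SiftCall,
    TrioRecord,
)
from .sv import Caller, ExonInterval, SVCall, SVType, write_sv_calls

__all__ = [
    "PlantSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate",
    "default_plants",
    "recover",
    "RecoverySummary",
]

TEMPLATES = (
    "pathogenic_plof",
    "likely_pathogenic_missense",
    "vus_plof",
    "vus_missense",
    "benign_common",
    "nmd_escape_plof",
    "denovo_damaging",
    "inherited_unaffected",
)

#: Expected cascade outcome and tier for each template, by construction.
TEMPLATE_EXPECTATIONS: dict[str, tuple[bool, Optional[str]]] = {
    "pathogenic_plof": (True, "pathogenic"),
    "likely_pathogenic_missense": (True, "likely_pathogenic"),
    "vus_plof": (True, "vus"),
    "vus_missense": (True, "vus"),
    "benign_common": (False, None),
    "nmd_escape_plof": (True, "vus"),
    "denovo_damaging": (True, "vus"),
    "inherited_unaffected": (True, "vus"),
}


@dataclass(frozen=True)
class PlantSpec:
    """One planted variant: a template instantiated in a target proband."""

    template: str
    proband: str
    expected_survival: bool = True
    expected_tier: Optional[str] = None

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        survival, tier = TEMPLATE_EXPECTATIONS[self.template]
        if self.expected_survival != survival or self.expected_tier != tier:
            raise ValueError(
                f"{self.template}: expected fields inconsistent with template"
            )


def _spec(template: str, proband: str) -> PlantSpec:
    survival, tier = TEMPLATE_EXPECTATIONS[template]
    return PlantSpec(template, proband, survival, tier)


def default_plants(n_trios: int = 10, n_singletons: int = 13) -> tuple[PlantSpec, ...]:
    """One plant of each template, spread over distinct probands.

    Templates whose target proband does not exist in a smaller cohort are
    omitted.
    """
    singleton_templates = (
        "pathogenic_plof", "likely_pathogenic_missense", "vus_plof",
        "vus_missense", "benign_common", "nmd_escape_plof",
        "inherited_unaffected",
    )
    plants = [
        _spec(template, f"si{i:02d}")
        for i, template in enumerate(singleton_templates, start=1)
        if i <= n_singletons
    ]
    if n_trios >= 1:
        plants.append(_spec("denovo_damaging", "tr01"))
    return tuple(plants)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the generator."""

    n_trios: int = 10
    n_singletons: int = 13
    variants_per_proband: int = 60
    denovo_rate: float = 1.2          # Poisson mean per trio proband
    af_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mean_depth: float = 33.0
    plants: tuple[PlantSpec, ...] = field(default_factory=default_plants)
    plant_qualifying_sv: bool = False
    svs_per_proband: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trios, self.n_singletons, self.variants_per_proband) < 0:
            raise ValueError("counts must be non-negative")
        if abs(sum(self.af_weights) - 1.0) > 1e-9:
            raise ValueError("af_weights must sum to 1")
        known = set(self.trio_probands) | set(self.singleton_probands)
        for plant in self.plants:
            if plant.proband not in known:
                raise ValueError(f"plant targets unknown proband {plant.proband!r}")
            trio_target = plant.proband in self.trio_probands
            if plant.template == "denovo_damaging" and not trio_target:
                raise ValueError("denovo_damaging must target a trio proband")
            if plant.template != "denovo_damaging" and trio_target:
                raise ValueError(
                    f"{plant.template} targets singleton designs, got {plant.proband!r}"
                )

    @property
    def trio_probands(self) -> tuple[str, ...]:
        return tuple(f"tr{i:02d}" for i in range(1, self.n_trios + 1))

    @property
    def singleton_probands(self) -> tuple[str, ...]:
        return tuple(f"si{i:02d}" for i in range(1, self.n_singletons + 1))


@dataclass
class SyntheticCohort:
    """The generated bundle, in memory and writable to standard formats."""

    config: CohortConfig
    records: list[CohortRecord]
    trios: list[TrioRecord]
    truth: pd.DataFrame
    evidence: dict[str, GeneEvidence]
    contexts: dict[tuple, VariantContext]
    sv_pair_based: list[SVCall]
    sv_depth_based: list[SVCall]
    sv_parental: list[SVCall]
    exons: list[ExonInterval]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "annotations": outdir / "annotations.tsv",
            "pedigree": outdir / "pedigree.tsv",
            "truth": outdir / "truth.tsv",
            "gene_evidence": outdir / "gene_evidence.tsv",
            "variant_context": outdir / "variant_context.tsv",
            "sv_pair_based": outdir / "sv_pair_based.tsv",
            "sv_depth_based": outdir / "sv_depth_based.tsv",
            "sv_parental": outdir / "sv_parental.tsv",
            "exons": outdir / "exons.tsv",
        }
        write_cohort(self.records, self.trios, paths["vcf"],
                     paths["annotations"], paths["pedigree"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene": ev.gene,
                    "established_ndd_gene": int(ev.established_ndd_gene),
                    "lof_mechanism": int(ev.lof_mechanism),
                    "missense_mechanism": int(ev.missense_mechanism),
                    "causal_cluster": ";".join(f"{lo}-{hi}" for lo, hi in ev.causal_cluster) or ".",
                    "domain_critical": int(ev.domain_critical),
                    "phenotype_similarity": ev.phenotype_similarity.value,
                    "notes": ev.notes or ".",
                }
                for ev in self.evidence.values()
            ]
        ).to_csv(paths["gene_evidence"], sep="\t", index=False)
        ctx_rows = []
        key_to_variant = {r.variant.key: r.variant for r in self.records}
        for (proband, key), ctx in sorted(self.contexts.items()):
            ctx_rows.append(
                {
                    "proband": proband,
                    "gene": key_to_variant[key].gene,
                    "inheritance": ctx.inheritance.value,
                    "clinvar": ctx.clinvar.value,
                    "protein_position": ctx.protein_position
                    if ctx.protein_position is not None else ".",
                }
            )
        pd.DataFrame(
            ctx_rows,
            columns=["proband", "gene", "inheritance", "clinvar", "protein_position"],
        ).to_csv(paths["variant_context"], sep="\t", index=False)
        write_sv_calls(self.sv_pair_based, paths["sv_pair_based"])
        write_sv_calls(self.sv_depth_based, paths["sv_depth_based"])
        write_sv_calls(self.sv_parental, paths["sv_parental"])
        pd.DataFrame(
            [
                {"chrom": e.chrom, "start": e.start, "end": e.end,
                 "gene": e.gene, "pli": e.pli}
                for e in self.exons
            ]
        ).to_csv(paths["exons"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# generation internals

_BASES = np.array(list("ACGT"))
_AF_COMPONENTS = ("common", "low_frequency", "rare", "absent")


class _Generator:
    def __init__(self, config: CohortConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.used_keys: set[tuple] = set()
        self.samples: list[str] = []
        self.trios: list[TrioRecord] = []
        for pid in config.trio_probands:
            self.trios.append(TrioRecord(pid, f"{pid}-fa", f"{pid}-mo"))
            self.samples += [pid, f"{pid}-fa", f"{pid}-mo"]
        for pid in config.singleton_probands:
            self.trios.append(TrioRecord(pid))
            self.samples.append(pid)

    # -- low-level draws ----------------------------------------------------

    def _position(self) -> tuple[str, int]:
        while True:
            chrom = str(self.rng.integers(1, 23))
            pos = int(self.rng.integers(1_000_000, 200_000_000))
            if (chrom, pos) not in self.used_keys:
                self.used_keys.add((chrom, pos))
                return chrom, pos

    def _alleles(self) -> tuple[str, str]:
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        return str(ref), str(alt)

    def _depth_pair(self, gt: Genotype) -> tuple[int, int]:
        total = max(8, int(self.rng.poisson(self.config.mean_depth)))
        if gt is Genotype.het:
            alt = int(self.rng.binomial(total, 0.5))
            alt = min(max(alt, 1), total - 1)
            return total - alt, alt
        if gt is Genotype.hom_alt:
            return 0, total
        return total, 0

    def _population_af(self) -> float:
        component = self.rng.choice(4, p=np.asarray(self.config.af_weights))
        if component == 0:
            return float(self.rng.uniform(0.05, 0.5))
        if component == 1:
            return float(self.rng.uniform(0.005, 0.05))
        if component == 2:
            return float(self.rng.uniform(1e-6, 3.2e-4))
        return 0.0

    def _benign_annotation(self, chrom: str, pos: int, ref: str, alt: str,
                           gene: str) -> AnnotatedVariant:
        """Background variant: tolerant gene, benign scores, non-pLoF class."""
        consequence = Consequence(
            str(self.rng.choice(
                ["missense", "synonymous", "other", "inframe_indel"],
                p=[0.5, 0.3, 0.15, 0.05],
            ))
        )
        af = self._population_af()
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{gene}", consequence=consequence,
            cdna_change=f"c.{pos % 999 + 1}{ref}>{alt}",
            protein_change=".",
            gnomad_af=af, kaviar_af=af,
            pli=float(self.rng.uniform(0.0, 0.5)),
            mis_z=float(np.clip(self.rng.normal(0.0, 1.0), -4.0, 2.0)),
            local_tolerance=LocalTolerance(
                str(self.rng.choice(["tolerant", "neutral", "slightly_tolerant"]))
            ),
            sift=SiftCall.T, polyphen=PolyphenCall.T,
            revel=float(self.rng.uniform(0.0, 0.2)),
            gerp=float(self.rng.uniform(-2.0, 2.0)),
            brain_expressed=bool(self.rng.random() < 0.9),
            in_segdup=bool(self.rng.random() < 0.02),
        )

    # -- genotype assembly --------------------------------------------------

    def _full_genotypes(self, carriers: dict[str, Genotype],
                        fixed_depths: Optional[tuple[int, int]] = None,
                        parent_alt_noise: Sequence[str] = ()) -> dict[str, GenotypeCall]:
        calls = {}
        for sid in self.samples:
            gt = carriers.get(sid, Genotype.hom_ref)
            if fixed_depths is not None and gt is not Genotype.hom_ref:
                depths = fixed_depths
            else:
                depths = self._depth_pair(gt)
            if sid in parent_alt_noise:
                depths = (depths[0], max(depths[1], 1))
            calls[sid] = GenotypeCall(sample_id=sid, gt=gt, allele_depths=depths)
        return calls

    # -- background ---------------------------------------------------------

    def background_records(self) -> list[CohortRecord]:
        records = []
        counter = 0
        for trio in self.trios:
            pid = trio.proband_id
            for _ in range(self.config.variants_per_proband):
                chrom, pos = self._position()
                ref, alt = self._alleles()
                counter += 1
                variant = self._benign_annotation(chrom, pos, ref, alt,
                                                  gene=f"BG{counter:05d}")
                carriers = {pid: Genotype.het}
                if trio.design == "trio":
                    transmitting = str(self.rng.choice(list(trio.parent_ids)))
                    carriers[transmitting] = Genotype.het
                records.append(
                    CohortRecord(variant=variant,
                                 genotypes=self._full_genotypes(carriers))
                )
            if trio.design == "trio" and self.config.denovo_rate > 0:
                for _ in range(int(self.rng.poisson(self.config.denovo_rate))):
                    chrom, pos = self._position()
                    ref, alt = self._alleles()
                    counter += 1
                    variant = self._benign_annotation(chrom, pos, ref, alt,
                                                      gene=f"BG{counter:05d}")
                    records.append(
                        CohortRecord(
                            variant=variant,
                            genotypes=self._full_genotypes({pid: Genotype.het}),
                        )
                    )
        return records

    # -- plants -------------------------------------------------------------

    def plant_record(self, plant: PlantSpec, index: int
                     ) -> tuple[CohortRecord, GeneEvidence, VariantContext, dict]:
        chrom, pos = self._position()
        ref, alt = self._alleles()
        gene = f"PL_{plant.template.upper()}_{index:02d}"
        base = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{gene}", gnomad_af=0.0, kaviar_af=0.0,
            brain_expressed=True, in_segdup=False,
            filter_status=FilterStatus.pass_,
        )
        evidence = GeneEvidence(gene=gene)
        inheritance = Inheritance.unknown
        protein_position: Optional[int] = None
        t = plant.template
        if t == "pathogenic_plof":
            base.update(consequence=Consequence.frameshift, pli=0.98,
                        dist_to_transcript_end=600, affects_protein_domain=True,
                        protein_change="p.Q100fs")
            evidence = GeneEvidence(gene, True, True, False, (), False,
                                    PhenotypeSimilarity.overlapping)
        elif t == "likely_pathogenic_missense":
            base.update(consequence=Consequence.missense, pli=0.95, mis_z=3.5,
                        local_tolerance=LocalTolerance.intolerant,
                        sift=SiftCall.D, polyphen=PolyphenCall.D,
                        revel=0.9, gerp=5.0, protein_change="p.R150W")
            evidence = GeneEvidence(gene, True, False, True, ((100, 200),), False,
                                    PhenotypeSimilarity.overlapping)
            protein_position = 150
        elif t == "vus_plof":
            base.update(consequence=Consequence.stop_gain, pli=0.97,
                        dist_to_transcript_end=500, protein_change="p.R80X")
        elif t == "vus_missense":
            base.update(consequence=Consequence.missense, pli=0.96, mis_z=3.2,
                        local_tolerance=LocalTolerance.intolerant,
                        sift=SiftCall.D, polyphen=PolyphenCall.D,
                        revel=0.8, gerp=4.5, protein_change="p.G50R")
            protein_position = 50
        elif t == "benign_common":
            af = 0.05
            base.update(consequence=Consequence.missense, pli=0.95, mis_z=3.0,
                        local_tolerance=LocalTolerance.intolerant,
                        sift=SiftCall.D, polyphen=PolyphenCall.D,
                        revel=0.8, gerp=4.0, gnomad_af=af, kaviar_af=af,
                        protein_change="p.A10T")
        elif t == "nmd_escape_plof":
            base.update(consequence=Consequence.frameshift, pli=0.95,
                        dist_to_transcript_end=30, affects_protein_domain=True,
                        protein_change="p.E990fs")
            evidence = GeneEvidence(gene, True, True, False, (), False,
                                    PhenotypeSimilarity.overlapping)
        elif t == "denovo_damaging":
            base.update(consequence=Consequence.stop_gain, pli=0.99,
                        dist_to_transcript_end=400, protein_change="p.R275X")
        elif t == "inherited_unaffected":
            base.update(consequence=Consequence.frameshift, pli=0.95,
                        dist_to_transcript_end=300, protein_change="p.K200fs")
            inheritance = Inheritance.inherited_unaffected_parent

        variant = AnnotatedVariant(**base)
        carriers = {plant.proband: Genotype.het}
        record = CohortRecord(
            variant=variant,
            genotypes=self._full_genotypes(carriers, fixed_depths=(16, 16)),
        )
        context = VariantContext(
            inheritance=inheritance,
            novel_in_population=variant.max_db_af == 0.0,
            nmd_predicted=(
                variant.dist_to_transcript_end is not None
                and variant.dist_to_transcript_end > 50
            ),
            protein_position=protein_position,
            conserved_residue=variant.gerp is not None and variant.gerp > 2.0,
        )
        truth_row = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "proband": plant.proband, "template": t, "gene": gene,
            "expected_survival": plant.expected_survival,
            "expected_tier": plant.expected_tier or ".",
        }
        return record, evidence, context, truth_row

    # -- structural variants ------------------------------------------------

    def sv_callsets(self) -> tuple[list[SVCall], list[SVCall], list[SVCall],
                                   list[ExonInterval]]:
        """Dual-caller SV calls with breakpoint jitter, plus an exon table.

        Exons of intolerant genes sit on chromosomes 1-11; all background
        SVs are placed on chromosomes 12-22, so by construction no
        background SV can yield an exonic intolerant candidate.  Each trio
        proband gets inherited deletions (present in a parent's pair-based
        calls) and one de novo deletion.
        """
        rng = self.rng
        exons = []
        for g in range(30):
            chrom = str(g % 11 + 1)
            start = 5_000_000 + g * 2_000_000
            pli = 0.99 if g % 3 == 0 else float(rng.uniform(0.0, 0.5))
            exons.append(ExonInterval(gene=f"SVG{g:02d}", chrom=chrom,
                                      start=start, end=start + 5_000, pli=pli))
        pair_calls, depth_calls, parental = [], [], []
        _DEL = SVType.deletion

        def jittered(sample: str, chrom: str, start: int, size: int) -> None:
            end = start + size - 1
            pair_calls.append(SVCall(Caller.pair_based, _DEL, chrom, start, end, sample))
            js = int(rng.integers(-3000, 3001))
            je = int(rng.integers(-3000, 3001))
            depth_calls.append(
                SVCall(Caller.depth_based, _DEL, chrom,
                       max(1, start + js), max(1, start + js) + max(size + je, size // 2) - 1,
                       sample)
            )

        for trio in self.trios:
            pid = trio.proband_id
            for k in range(self.config.svs_per_proband):
                chrom = str(int(rng.integers(12, 23)))
                start = int(rng.integers(1_000_000, 150_000_000))
                size = int(rng.integers(5_000, 80_000))
                jittered(pid, chrom, start, size)
                if trio.design == "trio":
                    # inherited: the pair-based caller also sees it in a parent
                    parent = str(rng.choice(list(trio.parent_ids)))
                    parental.append(
                        SVCall(Caller.pair_based, _DEL, chrom,
                               start + int(rng.integers(-2000, 2001)),
                               start + size - 1 + int(rng.integers(-2000, 2001)),
                               parent)
                    )
        if self.config.plant_qualifying_sv:
            # de novo deletion across an intolerant gene's exon (SVG00, chrom 1)
            target = self.trios[0].proband_id
            jittered(target, "1", 5_000_000 - 10_000, 30_000)
        return pair_calls, depth_calls, parental, exons


def generate(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort bundle; identical seeds give identical bundles."""
    config = config or CohortConfig()
    gen = _Generator(config)

    records: list[CohortRecord] = []
    evidence: dict[str, GeneEvidence] = {}
    contexts: dict[tuple, VariantContext] = {}
    truth_rows = []
    for index, plant in enumerate(config.plants):
        record, ev, ctx, truth_row = gen.plant_record(plant, index)
        records.append(record)
        evidence[ev.gene] = ev
        contexts[(plant.proband, record.variant.key)] = ctx
        truth_rows.append(truth_row)
    records.extend(gen.background_records())
    records.sort(key=lambda r: (int(r.variant.chrom), r.variant.pos))

    pair_calls, depth_calls, parental, exons = gen.sv_callsets()
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "proband", "template", "gene",
                 "expected_survival", "expected_tier"],
    )
    return SyntheticCohort(
        config=config, records=records, trios=gen.trios, truth=truth,
        evidence=evidence, contexts=contexts,
        sv_pair_based=pair_calls, sv_depth_based=depth_calls,
        sv_parental=parental, exons=exons,
    )


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass
class RecoverySummary:
    survival_sensitivity: float
    survival_specificity: float
    tier_accuracy: float
    per_template: pd.DataFrame

    @property
    def perfect(self) -> bool:
        return (
            self.survival_sensitivity == 1.0
            and self.survival_specificity == 1.0
            and self.tier_accuracy == 1.0
        )


def recover(
    cohort: SyntheticCohort,
    verdicts: Sequence[FilterVerdict],
    classified: Sequence[ClassifiedVariant],
) -> RecoverySummary:
    """Score pipeline outputs against the cohort's ground-truth manifest.

    Survival sensitivity/specificity cover the planted variants (expected
    survivors vs expected non-survivors, the latter pooled with all
    background variants, none of which is constructed to survive); tier
    accuracy covers planted expected survivors only.
    """
    survived_keys = {
        (v.proband_id, v.key) for v in verdicts if v.survived
    }
    tier_by_key = {
        (cv.proband_id, cv.variant.key): cv.tier.value.value for cv in classified
    }
    truth_keys = set()
    tp = fn = tn = fp = 0
    tier_hits = tier_total = 0
    rows = []
    for row in cohort.truth.to_dict(orient="records"):
        key = (row["proband"], (str(row["chrom"]), int(row["pos"]),
                                str(row["ref"]), str(row["alt"])))
        truth_keys.add(key)
        observed = key in survived_keys
        expected = bool(row["expected_survival"])
        tp += observed and expected
        fn += expected and not observed
        fp += observed and not expected
        tn += (not expected) and (not observed)
        tier_ok: Optional[bool] = None
        if expected:
            tier_total += 1
            tier_ok = tier_by_key.get(key) == row["expected_tier"]
            tier_hits += bool(tier_ok)
        rows.append(
            {
                "template": row["template"], "proband": row["proband"],
                "expected_survival": expected, "observed_survival": observed,
                "expected_tier": row["expected_tier"],
                "observed_tier": tier_by_key.get(key, "."),
                "tier_correct": tier_ok,
            }
        )
    # background: every surviving key not in the manifest is a false positive
    background_fp = sum(1 for key in survived_keys if key not in truth_keys)
    fp += background_fp
    n_background = sum(
        1
        for v in verdicts
        if (v.proband_id, v.key) not in truth_keys
    )
    tn += n_background - background_fp

    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    acc = tier_hits / tier_total if tier_total else 1.0
    return RecoverySummary(sens, spec, acc, pd.DataFrame(rows))


def run_recovery(cohort: SyntheticCohort, config: FilterConfig | None = None
                 ) -> tuple[list[FilterVerdict], list[ClassifiedVariant], RecoverySummary]:
    """Full pipeline on a synthetic bundle: cascade, classify, score."""
    config = config or FilterConfig()
    verdicts = run_cascade(cohort.records, cohort.trios, config)
    by_key = {r.variant.key: r.variant for r in cohort.records}
    survivors = [
        (v.proband_id, by_key[v.key], v) for v in verdicts if v.survived
    ]
    contexts = {}
    for pid, variant, verdict in survivors:
        ctx = cohort.contexts.get((pid, variant.key))
        if ctx is None:
            ctx = build_context(variant, config)
        contexts[(pid, variant.key)] = ctx
    classified = classify_cohort(survivors, cohort.evidence, contexts)
    return verdicts, classified, recover(cohort, verdicts, classified)
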