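"""Domain types for annotated variants, genotypes, pedigrees and thresholds.

The in-memory unit of the pipeline is an :class:`AnnotatedVariant` — one
VCF record joined with every annotation field the downstream filter cascade
consumes (population frequencies, gene constraint, impact predictors, brain
expression, transcript geometry) — together with per-sample
:class:`GenotypeCall` objects carrying genotype and allele depths.

All numeric annotations that may be unavailable are represented as ``None``,
never as 0; every predicate downstream documents how it treats absence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .af_threshold import default_maf_ceiling

__all__ = [
    "Consequence",
    "PLOF_CONSEQUENCES",
    "MISSENSE_LIKE",
    "LocalTolerance",
    "INTOLERANT_CATEGORIES",
    "TOLERANT_CATEGORIES",
    "SiftCall",
    "PolyphenCall",
    "SpliceSiteClass",
    "FilterStatus",
    "Genotype",
    "GenotypeCall",
    "AnnotatedVariant",
    "TrioRecord",
    "FilterConfig",
    "VariantKey",
    "qc_pass",
]


class Consequence(str, enum.Enum):
    missense = "missense"
    stop_gain = "stop_gain"
    frameshift = "frameshift"
    splice = "splice"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    other = "other"


#: Probable loss-of-function classes (stop-gain, frameshift, essential splice).
PLOF_CONSEQUENCES = frozenset(
    {Consequence.stop_gain, Consequence.frameshift, Consequence.splice}
)
#: Classes routed through the missense (gene-constraint) filters.
MISSENSE_LIKE = frozenset({Consequence.missense, Consequence.inframe_indel})


class LocalTolerance(str, enum.Enum):
    """Per-residue regional missense tolerance category (Metadome-style)."""

    highly_intolerant = "highly_intolerant"
    intolerant = "intolerant"
    slightly_intolerant = "slightly_intolerant"
    neutral = "neutral"
    slightly_tolerant = "slightly_tolerant"
    tolerant = "tolerant"
    unavailable = "unavailable"


#: Categories counting as an intolerant locus for the missense gene filter.
INTOLERANT_CATEGORIES = frozenset(
    {
        LocalTolerance.highly_intolerant,
        LocalTolerance.intolerant,
        LocalTolerance.slightly_intolerant,
    }
)
#: Categories counting as a tolerant region for the de novo evaluation rule.
TOLERANT_CATEGORIES = frozenset(
    {
        LocalTolerance.slightly_tolerant,
        LocalTolerance.tolerant,
        LocalTolerance.neutral,
    }
)


class SiftCall(str, enum.Enum):
    D = "D"  # deleterious
    T = "T"  # tolerated
    unavailable = "unavailable"


class PolyphenCall(str, enum.Enum):
    D = "D"  # probably damaging
    P = "P"  # possibly damaging
    T = "T"  # benign
    unavailable = "unavailable"


class SpliceSiteClass(str, enum.Enum):
    main_donor_acceptor = "main_donor_acceptor"
    other = "other"
    not_splice = "not_splice"


class FilterStatus(str, enum.Enum):
    pass_ = "pass"
    fail = "fail"


class Genotype(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call with per-allele supporting read counts."""

    sample_id: str
    gt: Genotype
    allele_depths: tuple[int, int] = (0, 0)  # (ref_reads, alt_reads)

    def __post_init__(self) -> None:
        ref_reads, alt_reads = self.allele_depths
        if ref_reads < 0 or alt_reads < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def carries_alt(self) -> bool:
        return self.gt in (Genotype.het, Genotype.hom_alt)


VariantKey = tuple[str, int, str, str]


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be within [0, 1], got {value!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A single variant with every annotation the filter cascade reads.

    Positions are 1-based VCF coordinates; indels are assumed to be
    left-normalized by the producer. ``dist_to_transcript_end`` is measured
    in coding base pairs from the variant to the transcript stop.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: Consequence
    cdna_change: str = ""
    protein_change: str = ""
    gnomad_af: float = 0.0
    kaviar_af: float = 0.0
    pli: Optional[float] = None
    mis_z: Optional[float] = None
    local_tolerance: LocalTolerance = LocalTolerance.unavailable
    sift: SiftCall = SiftCall.unavailable
    polyphen: PolyphenCall = PolyphenCall.unavailable
    revel: Optional[float] = None
    gerp: Optional[float] = None
    brain_expressed: bool = True
    in_segdup: bool = False
    filter_status: FilterStatus = FilterStatus.pass_
    dist_to_transcript_end: Optional[int] = None
    affects_protein_domain: bool = False
    splice_site_class: SpliceSiteClass = SpliceSiteClass.not_splice

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        _check_fraction("gnomad_af", self.gnomad_af)
        _check_fraction("kaviar_af", self.kaviar_af)
        _check_fraction("pli", self.pli)
        _check_fraction("revel", self.revel)
        if self.dist_to_transcript_end is not None and self.dist_to_transcript_end < 0:
            raise ValueError("dist_to_transcript_end must be non-negative")
        is_splice = self.consequence is Consequence.splice
        has_splice_class = self.splice_site_class is not SpliceSiteClass.not_splice
        if is_splice != has_splice_class:
            raise ValueError(
                "consequence 'splice' must coincide with a splice_site_class "
                "other than 'not_splice' (and vice versa)"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_db_af(self) -> float:
        """The stricter of the two population database frequencies."""
        return max(self.gnomad_af, self.kaviar_af)

    @property
    def is_plof(self) -> bool:
        return self.consequence in PLOF_CONSEQUENCES


@dataclass(frozen=True)
class TrioRecord:
    """Pedigree line: a proband and, for trio designs, both parents."""

    proband_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError(
                f"proband {self.proband_id}: trio design requires both parents"
            )

    @property
    def design(self) -> str:
        return "trio" if self.father_id is not None else "singleton"

    @property
    def parent_ids(self) -> tuple[str, ...]:
        if self.father_id is None:
            return ()
        return (self.father_id, self.mother_id)


@dataclass(frozen=True)
class FilterConfig:
    """Every numeric threshold of the prioritization cascade.

    Defaults are the study conditions: MAF ceiling from the credible-AF
    framework (2.9% prevalence, 0.02 heterogeneity, 90% penetrance), pLI
    > 0.9 and MIS_Z > 2.5 for gene intolerance, GERP > 2 and REVEL > 0.5
    for missense impact, a 50 coding-bp end-of-transcript window for
    truncating variants, and the de novo tolerance cut-offs REVEL < 0.25
    and MIS_Z < 3.
    """

    maf_ceiling: float = field(default_factory=default_maf_ceiling)
    min_reads_per_allele: int = 4
    pli_min: float = 0.9
    mis_z_min: float = 2.5
    gerp_min: float = 2.0
    revel_min: float = 0.5
    nmd_end_window_bp: int = 50
    denovo_revel_tolerated_max: float = 0.25
    denovo_mis_z_min: float = 3.0
    # Behavioural switches (defaults conservative).
    qc_apply_to_parents: bool = False
    denovo_require_zero_parent_alt_reads: bool = True
    missing_scores_nonblocking: bool = False

    def __post_init__(self) -> None:
        for name in (
            "maf_ceiling", "min_reads_per_allele", "pli_min", "mis_z_min",
            "gerp_min", "revel_min", "nmd_end_window_bp",
            "denovo_revel_tolerated_max", "denovo_mis_z_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("maf_ceiling", "pli_min", "revel_min", "denovo_revel_tolerated_max"):
            _check_fraction(name, getattr(self, name))


class MissingGenotypeError(KeyError):
    """A required sample genotype is absent from the cohort."""


def _allele_depth_ok(call: GenotypeCall, min_reads: int) -> bool:
    """Read-support rule for one call: every carried allele needs coverage.

    het: both alleles carried, both depths must reach ``min_reads``;
    hom_ref / hom_alt: only the carried allele's depth is checked;
    missing genotype: fails (cannot establish support).
    """
    ref_reads, alt_reads = call.allele_depths
    if call.gt is Genotype.het:
        return ref_reads >= min_reads and alt_reads >= min_reads
    if call.gt is Genotype.hom_ref:
        return ref_reads >= min_reads
    if call.gt is Genotype.hom_alt:
        return alt_reads >= min_reads
    return False


def qc_pass(
    variant: AnnotatedVariant,
    genotypes: Mapping[str, GenotypeCall],
    proband_id: str,
    config: FilterConfig,
    parent_ids: tuple[str, ...] = (),
) -> bool:
    """Genotype-level QC: caller FILTER, segmental duplications, read support.

    A variant passes iff its FILTER verdict is pass, it does not fall in a
    known segmental duplication, and the proband's carried alleles each have
    at least ``config.min_reads_per_allele`` supporting reads (≤ 3 reads on
    either allele of a het call fails).  With ``config.qc_apply_to_parents``
    the same read-support rule is applied to the listed parents.
    """
    if proband_id not in genotypes:
        raise MissingGenotypeError(proband_id)
    if variant.filter_status is not FilterStatus.pass_:
        return False
    if variant.in_segdup:
        return False
    if not _allele_depth_ok(genotypes[proband_id], config.min_reads_per_allele):
        return False
    if config.qc_apply_to_parents:
        for pid in parent_ids:
            if pid in genotypes and not _allele_depth_ok(
                genotypes[pid], config.min_reads_per_allele
            ):
                return False
    return True
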