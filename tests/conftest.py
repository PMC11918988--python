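"""Shared builders for compact test cohorts."""

from __future__ import annotations

import pytest

from varsieve.model import (
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
)


@pytest.fixture
def config() -> FilterConfig:
    return FilterConfig()


def make_variant(**overrides) -> AnnotatedVariant:
    """A missense variant that passes every default filter, unless overridden."""
    base = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        gene="GENE1",
        transcript="NM_000001",
        consequence=Consequence.missense,
        gnomad_af=0.0,
        kaviar_af=0.0,
        pli=0.95,
        mis_z=3.0,
        local_tolerance=LocalTolerance.intolerant,
        sift=SiftCall.D,
        polyphen=PolyphenCall.D,
        revel=0.8,
        gerp=4.0,
        brain_expressed=True,
    )
    base.update(overrides)
    if base["consequence"] is Consequence.splice and "splice_site_class" not in overrides:
        base["splice_site_class"] = SpliceSiteClass.main_donor_acceptor
    return AnnotatedVariant(**base)


def het(sample: str, ref_reads: int = 15, alt_reads: int = 15) -> GenotypeCall:
    return GenotypeCall(sample, Genotype.het, (ref_reads, alt_reads))


def hom_ref(sample: str, depth: int = 30, alt_reads: int = 0) -> GenotypeCall:
    return GenotypeCall(sample, Genotype.hom_ref, (depth, alt_reads))


def hom_alt(sample: str, depth: int = 30) -> GenotypeCall:
    return GenotypeCall(sample, Genotype.hom_alt, (0, depth))


@pytest.fixture
def trio() -> TrioRecord:
    return TrioRecord("kid", "dad", "mum")


@pytest.fixture
def singleton() -> TrioRecord:
    return TrioRecord("solo")
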