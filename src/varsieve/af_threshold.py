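"""Maximum credible population allele frequency for a dominant rare disorder.

A truly causal variant for a Mendelian disorder cannot be more frequent in
the general population than the disorder itself allows: with prevalence
``P``, a maximum share ``h`` of cases attributable to any single variant
(allelic/genetic heterogeneity) and penetrance ``f``, a heterozygous causal
allele has population frequency at most ``P * h / (2 * f)`` (the factor 2
converting the frequency of carrier genotypes to an allele frequency).
Population databases such as gnomAD and Kaviar can then be used to discard
any candidate whose observed frequency exceeds this ceiling.

For idiopathic speech delay the disorder prevalence itself is derived from
the prevalence of speech delay in 4-8-year-olds (3.6%) times the share of
those cases without a motor speech disorder (82%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal

__all__ = [
    "AFFrameworkParams",
    "derive_prevalence",
    "max_credible_af",
    "round_sig",
    "truncate_sig",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class AFFrameworkParams:
    """Inputs to the allele-frequency ceiling for monoallelic inheritance.

    prevalence
        Fraction of the population affected by the disorder, in (0, 1].
    heterogeneity
        Maximum share of cases attributable to any one variant, in (0, 1].
    penetrance
        Probability that a carrier is affected, in (0, 1].
    """

    prevalence: float
    heterogeneity: float
    penetrance: float
    inheritance: str = "monoallelic"

    def __post_init__(self) -> None:
        for name in ("prevalence", "heterogeneity", "penetrance"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if self.inheritance != "monoallelic":
            raise ValueError("only monoallelic inheritance is supported")


def truncate_sig(x: float, sig_figs: int) -> float:
    """Truncate ``x`` toward zero to ``sig_figs`` significant figures."""
    if x == 0:
        return 0.0
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    d = Decimal(repr(x))
    exponent = d.adjusted() - (sig_figs - 1)
    return float(d.quantize(Decimal(1).scaleb(exponent), rounding=ROUND_DOWN))


def round_sig(x: float, sig_figs: int) -> float:
    """Round ``x`` to ``sig_figs`` significant figures (round half away)."""
    if x == 0:
        return 0.0
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    ndigits = sig_figs - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def derive_prevalence(base_prevalence: float, subtype_fraction: float, sig_figs: int = 2) -> float:
    """Prevalence of a disorder subtype, reported at fixed significant figures.

    ``base_prevalence * subtype_fraction`` truncated toward zero to
    ``sig_figs`` significant figures.  Truncation (not round-half) is the
    package's reporting convention for derived prevalences: a subtype cannot
    be reported as more prevalent than the product supports.

    >>> derive_prevalence(0.036, 0.82, 2)
    0.029
    """
    if base_prevalence <= 0 or subtype_fraction <= 0:
        raise ValueError("prevalence inputs must be positive")
    if base_prevalence > 1 or subtype_fraction > 1:
        raise ValueError("prevalence inputs must be fractions <= 1")
    return truncate_sig(base_prevalence * subtype_fraction, sig_figs)


def max_credible_af(params: AFFrameworkParams | None = None, *,
                    prevalence: float | None = None,
                    heterogeneity: float | None = None,
                    penetrance: float | None = None) -> float:
    """Maximum credible population allele frequency (full precision).

    For monoallelic (heterozygous) inheritance::

        af_max = prevalence * heterogeneity / (2 * penetrance)

    Accepts either an :class:`AFFrameworkParams` or the three keyword
    fractions directly.  Display rounding to 2 significant figures is left
    to the caller (see :func:`round_sig`); comparisons should use the
    unrounded value or an explicitly rounded ceiling, never both.
    """
    if params is None:
        if None in (prevalence, heterogeneity, penetrance):
            raise ValueError("provide AFFrameworkParams or all three fractions")
        params = AFFrameworkParams(prevalence, heterogeneity, penetrance)
    return params.prevalence * params.heterogeneity / (2.0 * params.penetrance)


#: Study-condition defaults: speech-delay prevalence 2.9% (3.6% of
#: 4-8-year-olds times 82% without a motor speech disorder), lenient
#: heterogeneity (no single variant explains more than 2% of cases) and
#: penetrance 90%.
DEFAULT_PARAMS = AFFrameworkParams(
    prevalence=derive_prevalence(0.036, 0.82, 2),
    heterogeneity=0.02,
    penetrance=0.90,
)


def default_maf_ceiling() -> float:
    """The default MAF ceiling: the framework value at 2 significant figures."""
    return round_sig(max_credible_af(DEFAULT_PARAMS), 2)


def sensitivity_grid(prevalences, heterogeneities, penetrances):
    """Ceiling over a parameter grid, as a list of dict rows (for TSV output)."""
    rows = []
    for p in prevalences:
        for h in heterogeneities:
            for f in penetrances:
                rows.append({
                    "prevalence": p,
                    "heterogeneity": h,
                    "penetrance": f,
                    "max_credible_af": max_credible_af(AFFrameworkParams(p, h, f)),
                })
    return rows
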