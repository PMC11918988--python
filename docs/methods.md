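# Methods

## Scope and data model

The pipeline starts from called genotypes, not reads: its inputs are a
multi-sample VCF (GT and AD per sample; the FILTER column carrying the
caller's recalibration verdict), a tab-separated annotation table keyed by
(chrom, pos, ref, alt), a three-column pedigree, BED-like SV call tables
from two callers, and curated gene-evidence / variant-context tables.
Annotation values that can be unavailable (pLI, MIS_Z, REVEL, GERP,
regional tolerance, SIFT/PolyPhen calls, distance to transcript end) are
represented as absent, never as zero; each predicate documents how it
treats absence. Coordinates are 1-based VCF coordinates; indels are assumed
left-normalized by the producer and are not re-normalized.

## Allele-frequency ceiling

For a monoallelic disorder the ceiling is `prevalence × heterogeneity /
(2 × penetrance)`: the prevalence bounds the frequency of affected
genotypes, heterogeneity caps the share any one variant can explain,
penetrance converts affected frequency to carrier frequency, and the factor
2 converts heterozygous-genotype frequency to allele frequency. A biallelic
mode is deliberately not offered; the analysis this package implements
considers dominant acting variants only. Defaults: prevalence 0.029,
heterogeneity 0.02, penetrance 0.90, giving a ceiling of 3.2 × 10⁻⁴ at two
significant figures. Filtering compares the ceiling (rounded to 2
significant figures, matching how such thresholds are quoted and applied)
against the *maximum* of the two database frequencies — both databases are
cited as references, and under strict filtering the stricter combination is
the faithful reading.

Derived prevalences are truncated toward zero at the requested significant
figures rather than half-rounded (0.036 × 0.82 = 0.02952 reports as 0.029,
i.e. 2.9%): a subtype prevalence should not be reported above what the
product supports. This is the package's reporting convention and is applied
uniformly.

## QC and de novo rules

The read-support rule requires at least 4 reads for *each allele the
proband carries* (both alleles of a het call, the single allele of a
homozygous call); "3 or fewer reads supporting either allele" fails. By
default the rule applies to the proband only; `qc_apply_to_parents`
extends it to the parents, since the source analysis does not state which
convention it used.

De novo detection requires the child to carry the alternate allele and both
parents to be called homozygous reference *with zero alt-supporting reads*.
The zero-read requirement (switchable via
`denovo_require_zero_parent_alt_reads`) guards against under-called mosaic
or low-coverage transmission being misread as de novo.

## Missing-score policy in the missense filters

The conservative default is that an absent score fails its clause: unknown
constraint is not evidence of intolerance, and an absent predictor is not
evidence of impact. The published candidate list, however, retains one
missense variant whose regional-tolerance and predictor columns are all
unavailable, so the policy is exposed as a single switch
(`missing_scores_nonblocking`): when enabled, absent regional tolerance and
absent predictor values become non-blocking in the missense gene and impact
filters (clauses with observed values still bind). Table replay and the
acceptance script use the switch for the missense table, as the published
counts require; the default remains strict. In-frame indels always bypass
the per-substitution predictor filter (SIFT/PolyPhen/REVEL are undefined
for them) and are flagged "predictors unavailable" in the verdict.

## NMD and the end-of-transcript window

Truncating variants are predicted to trigger nonsense-mediated decay when
they lie more than 50 coding base pairs from the transcript end (strict
inequality at the boundary; distance measured in coding bases to the stop).
The canonical NMD rule references the last exon–exon junction rather than
the transcript end; the implemented window follows the rule as stated by
the source analysis, and the discrepancy is a known limitation. Truncations
inside the window are excluded from the pLoF route unless they disrupt a
protein domain — in which case they survive but are *not* NMD-predicted,
so they cannot reach the pathogenic tier through the haploinsufficiency
rule.

## SV concordance choices

"Twofold size difference" is enforced as a size *ratio* ≤ 2 and the 10 kb
breakpoint tolerance at *both* breakpoints: with only a one-breakpoint
rule, the size constraint would still admit grossly discordant intervals.
Calls pair one-to-one, greedily by smallest combined breakpoint distance
with ties broken by leftmost start — the source procedure names no pairing
scheme, and greedy matching is verified in tests against an exhaustive
oracle on instances up to 100 calls. Parental exclusion consults only the
pair-based caller's parental calls (the caller run jointly across the
pedigree). The consensus interval passed to the exon filter is the union
span of the two member calls; one overlapping base with one exon of a
pLI > 0.9 gene qualifies.

## Classification rule table

The engine encodes the dispositions a strict research-cohort analysis
produces, not the full ACMG/AMP catalog. Priority order R1 > R2 > R3 > R4 >
R5 is fixed: an existing ClinVar benign-side or conflicting interpretation
overrides everything (this is what keeps a variant that superficially meets
the likely-pathogenic surface criteria at VUS when interpretations
conflict); pathogenic requires an NMD-triggering truncation in an
established haploinsufficiency gene with a non-dissimilar phenotype;
likely-pathogenic requires an established missense-mechanism gene plus
novelty, conservation, passed impact filter and causal-cluster location;
everything else is VUS, with explicit demotion codes (outside cluster,
dissimilar phenotype, unestablished gene, inherited from an unaffected
parent, competing finding). Competing findings are resolved in two passes:
variants sharing a proband with a likely-pathogenic/pathogenic finding are
re-classified with the competing flag set; the flag can only demote. In the
pathological case of two likely-pathogenic findings in one proband, each
would demote the other in pass two; the cohorts this targets do not produce
that configuration, and the behaviour is deterministic.

Dual interpretations in the published tables ("VUS/likely benign") are
matched by requiring the engine's tier to be one of the listed options; the
ClinVar-sourced alternative appears in the rationale codes.

Causal-cluster intervals in the packaged gene-evidence table are
transcribed from published domain descriptions (SPTBN1 second calponin
homology domain ≈ residues 173–276; ARF3 switch-2 ≈ 70–80; NAA15 450–484;
CIC HMG-box ≈ 200–268) and are treated as exact interval inputs even where
the source language is approximate ("mainly located").

## Synthetic cohort generator

The generator emulates what the cascade observes, not genome biology:
background annotation scores are drawn from template-conditional
distributions (tolerant regional categories, pLI < 0.5, MIS_Z < 2,
REVEL < 0.2, benign SIFT/PolyPhen), so that no background variant can
satisfy the gene-intolerance clause — background survival is structurally
impossible, which is what makes planted-recovery sensitivity/specificity
exact rather than statistical. Consequences of background variants exclude
truncating classes for the same reason. What the generator therefore does
*not* emulate: linkage structure, mutational spectra, realistic gene-level
score correlations, multi-allelic sites, and annotation noise; passing
recovery tests shows the cascade implements its stated logic, not that it
would perform identically on real cohort data.

Defaults mirror the study conditions: 10 trios, 13 singletons, mean depth
33 (Poisson, het alt fraction binomial at 0.5, minimum total depth 8),
Poisson(1.2) background de novo events per trio proband, and a
four-component allele-frequency mixture (common U(0.05, 0.5), low-frequency
U(0.005, 0.05), rare U(10⁻⁶, 3.2 × 10⁻⁴), absent = 0) at equal weights.
`variants_per_proband` (default 60, i.e. ~1,400 sites cohort-wide) counts
proband-private carried sites; trio background variants are transmitted
from exactly one het parent. Planted variants receive fixed allele depths
(16, 16) so recovery isolates cascade logic from depth sampling noise. SV
call sets place all background events on chromosomes disjoint from the
intolerant-gene exons, with inter-caller breakpoint jitter within the
concordance tolerances and parental copies of inherited events; a
qualifying exonic de novo SV is planted only on request, matching the
study-shaped default of zero SV candidates.

All randomness flows from a single seed through one NumPy generator with a
fixed draw order; bundles are byte-identical across runs of the same seed.

## Problem sizes and numerical conventions

Property suites run on the default cohort (~1,400 variants, 23 probands),
SV oracle comparisons on ≤ 100 calls, and enumeration tests over the full
evidence/context enum space — sizes chosen so the whole suite completes in
well under a minute while every contract is exercised at the scale the
analysis actually uses. Threshold comparisons are strict inequalities
throughout (MAF < ceiling, pLI > 0.9, MIS_Z > 2.5, GERP > 2, REVEL > 0.5,
distance > 50 bp), matching the stated rules at their boundaries; tests pin
the boundary behaviour explicitly.

## Known limitations

* No compound-heterozygote or X-linked inheritance modelling; no biallelic
  allele-frequency ceiling.
* HGVS strings are opaque labels; protein positions used for cluster tests
  come from the context table, not from parsing.
* No liftover; fixture coordinates are GRCh37, and the fixture ref/alt
  alleles are reconstructed placeholders used only as join keys.
* The classifier is a faithful rule table for this analysis style, not a
  general clinical classifier.
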