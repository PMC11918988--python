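# varsieve

Rare-variant prioritization and five-tier classification for small
trio/singleton genome-sequencing cohorts, built around the analysis design
used for idiopathic speech delay: a cohort of 23 probands (10 parent–child
trios, 13 singletons) screened for high-penetrance coding variants under
strict, conjunctive filtering.

The package is for researchers analysing rare neurodevelopmental phenotypes
who start from called, annotated variants (VCF genotypes plus an annotation
table) rather than raw reads, and who need every filtering decision to be
auditable and testable.

## What it computes

**Allele-frequency ceiling.** A truly causal variant for a monoallelic
disorder with prevalence *P*, maximum per-variant share of cases *h*
(allelic heterogeneity), and penetrance *f* can have population allele
frequency at most

```
AF_max = P · h / (2 · f)
```

With speech-delay prevalence *P* = 2.9% (3.6% of 4–8-year-olds × 82%
without a motor speech disorder), *h* = 0.02 and *f* = 0.9, the ceiling is
3.2 × 10⁻⁴, applied strictly to the larger of the gnomAD and Kaviar
frequencies.

**Filter cascades.** Singleton probands: genotype QC (FILTER pass, no
segmental duplication, ≥ 4 reads per carried allele), absence from all trio
parents, the frequency ceiling, gene intolerance (pLI > 0.9 for truncating
variants; MIS_Z > 2.5 or pLI > 0.9 plus a regionally intolerant residue for
missense), predicted impact (essential splice sites only; truncations
within 50 coding bp of the transcript end dropped unless they hit a protein
domain; GERP > 2, REVEL > 0.5 and a damaging SIFT/PolyPhen call for
missense), and brain expression. Trio probands: de novo detection (both
parents homozygous reference with zero alt reads), the frequency ceiling,
brain expression, and a damaging-and-intolerant evaluation. All filters are
conjunctive, so the surviving set is independent of application order, and
each variant carries a per-filter audit trail.

**SV concordance.** Deletions/duplications are kept only when a read-pair
caller and a read-depth caller agree (size ratio ≤ 2, both breakpoints
within 10 kb), the event is absent from parental pair-based calls, and the
consensus interval overlaps an exon of a gene with pLI > 0.9.

**Five-tier classification.** Survivors are classified into pathogenic /
likely pathogenic / VUS / likely benign / benign by a fixed-priority rule
table combining ClinVar status, predicted nonsense-mediated decay, prior
gene–disease association and mechanism, causal-cluster location, population
novelty, residue conservation, inheritance, and competing findings within
the same proband. Every fired rule is emitted as a rationale code.

**Synthetic cohorts.** A seeded generator produces full cohort bundles
(VCF, annotation/pedigree/SV/evidence tables, ground-truth manifest) with
Mendelian transmission, Poisson de novo events, a mixture allele-frequency
spectrum, and planted variants for eight archetype templates, enabling
end-to-end recovery testing.

## Worked example

The packaged fixtures transcribe the study's three candidate-variant
tables. Replaying them:

```
$ varsieve replay-published
pLoF survivors (singletons): 5
missense survivors (singletons): 18
damaging de novo variants: 1 (KDR)
likely pathogenic missense: 2
diagnostic yield: 13%
  01 SETD1A: computed Pathogenic / printed Pathogenic
  02 PPP1R7: computed VUS / printed VUS
  ...
all dispositions match
```

The five truncating singleton variants all pass the pLoF route; of the six
de novo variants only the *KDR* stop-gain (pLI 1.00) is damaging and
intolerant; the classifier reproduces every printed disposition, including
the pathogenic *SETD1A* frameshift (NMD-predicted, established
haploinsufficiency gene), the likely pathogenic *SPTBN1* and *ARF3*
missense variants (novel, conserved, inside their causal clusters), and the
*TCERG1* splice variant demoted to VUS by the competing *SPTBN1* finding in
the same proband. Three solved probands out of 23 give the 13% diagnostic
yield.

A synthetic run with planted variants:

```
$ varsieve report --seed 1 --out run/
survival_sensitivity    1.0
survival_specificity    1.0
tier_accuracy           1.0
yield_percent           9.0
```

All eight planted templates behave as constructed (the templates expected
to survive do, the common benign variant is filtered, tiers match), and no
background variant survives.

Other subcommands: `af-ceiling` (ceiling and sensitivity grid), `simulate`,
`prioritize`, `sv-consensus`, `classify` — see `varsieve --help`.

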