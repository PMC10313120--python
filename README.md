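# hnf1a-reclass

Functional-evidence-driven re-interpretation of *HNF1A* variants found in
maturity-onset diabetes of the young (MODY).

Heterozygous loss-of-function variants in the transcription factor gene
*HNF1A* cause MODY3, a monogenic diabetes in which carriers of pathogenic
variants can often switch from insulin to oral sulfonylureas. Many *HNF1A*
variants found in clinical sequencing are initially reported as variants of
uncertain significance (VUS) because the standard ACMG/AMP annotation arms
(population frequency, hotspot location, in-silico predictors) are not
decisive. This package implements the re-interpretation pipeline that turns
wet-lab functional characterization — transactivation reporter assays in two
cell contexts, DNA binding, protein expression, nuclear localization, and
glucose-stimulated insulin secretion (GSIS) — plus categorical structural
predictions into **strength-modulated ACMG/AMP evidence codes**, and combines
them into the five-tier verdict (Pathogenic / Likely Pathogenic / VUS /
Likely Benign / Benign).

It is aimed at molecular geneticists and variant curators who have assay
readouts in hand and want a reproducible, auditable path from raw numbers to
a classification, including per-code rule traces.

## The model

**Assay normalization.** Reporter triplicates are normalized to the wild-type
construct: `%WT = 100 · mean(variant) / mean(WT)`, SD scaled by the WT mean,
significance by an unpaired two-tailed Student t-test on the raw triplicates
(pooled variance, df = 4 at n = 3; Welch optional), α = 0.05.

**Functional evidence (PS3/BS3).** With a secretion defect defined as
stimulated insulin < 8 µg/L:

| rule | condition | code |
|---|---|---|
| severe | ≥ 2 of {TA-HeLa, DNA binding, expression} < 40 %WT and secretion defect | PS3_Strong |
| escalation | severe rule and TA-HeLa < 25 %WT | PS3_VeryStrong |
| moderate | otherwise TA-HeLa < 60 %WT and secretion defect | PS3_Moderate |
| supporting | otherwise TA-HeLa < 65 %WT and secretion defect | PS3_Supporting |
| default | no damaging signature | BS3_Strong |

TA in INS-1 cells is not counted toward the severe tally (endogenous HNF1A
inflates it), nor is nuclear localization. All cut-offs are configurable
(`Thresholds`).

**Structural evidence (PP3).** Three categorical in-silico signals
(sequence-based stability, structure-based stability, molecular dynamics):
3 defect signals → PP3_Strong, 1–2 → PP3_Supporting, 0 → none. When any
structural analysis was run, its verdict supersedes an annotation-level PP3.

**Combining.** Pathogenic codes are scored additively with the Bayesian
point values (Supporting 1, Moderate 2, Strong 4, VeryStrong 8): ≥ 10 points
→ Pathogenic, 6–9 → Likely Pathogenic. Benign evidence is categorical (two
strong benign codes → Benign; one strong + one supporting, or two
supporting → Likely Benign), and a benign verdict stands only when the
pathogenic score is below 6; unresolved benign evidence yields VUS with a
conflict flag. The classical categorical combining rules are available as an
alternative policy (`--policy categorical-2015`) for comparison. Whether the
original curators used this exact arithmetic is not documented; this policy
is the minimal published framework consistent with all of their printed
verdicts.

## Worked example

```python
from hnf1a_reclass import classify_variant, load_study_fixture

study = load_study_fixture()          # 14 variants, 20 patients
fv = study.variant("p.Lys120Asn")     # TA-HeLa 47 %WT, stim. insulin 4 µg/L
res = classify_variant(fv.panel, fv.structural, fv.annotations)
print(res.classification.tier.value)
print(res.classification.pathogenic_points)
print(", ".join(res.evidence.to_strings()))
for t in res.traces:
    print(t)
```

prints

```
LikelyPathogenic
8
PS3_Moderate, PP3_Strong, PM2
PS3_moderate(ta_hela=47, dna_binding=92, protein_expression=76, gsis_stimulated=4, severe_assays=[]) -> PS3_Moderate
PP3_structural(sequence_based=destabilizing, structure_based=higher_destabilizing, md_simulation=defect, defect_signals=3) -> PP3_Strong
```

Transactivation at 47 %WT with defective insulin secretion grades a moderate
functional defect (2 points); all three structural analyses show defects
(PP3 at Strong, 4 points); with the prior PM2 annotation (2 points) the
variant totals 8 points — Likely Pathogenic, upgraded from its prior VUS.

The same pipeline runs from a shell:

```bash
hnf1a-reclass reclassify --out results/          # packaged study dataset
hnf1a-reclass reclassify --input my_variants.tsv --out results/
hnf1a-reclass reclassify --no-escalation --out results/
hnf1a-reclass summarize                          # clinical cohort summary
hnf1a-reclass simulate --seed 1 --n 100 --out sim/
hnf1a-reclass fixture --out tables/              # dump the study tables
```

`reclassify` writes a per-variant report (tier, points, fired evidence with
rule traces, expected tier side-by-side when the input carries one) and a
JSON summary with the tier tally and assay-defect group counts.

## Synthetic cohorts

`hnf1a_reclass.simulate` draws variant panels from four effect classes
(severe/moderate/mild loss of function, neutral) with class means and
annotation frequencies taken from the study panel, triplicate-scale Gaussian
noise truncated at zero, and clinical records with realistic missingness.
One integer seed determines the entire cohort byte-for-byte, which the test
suite uses for calibration and recovery checks.

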