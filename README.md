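# mmr-vclass

Evidence integration for classifying DNA mismatch-repair (MMR) gene
variants of uncertain significance (VUS) in Lynch syndrome work-up.

Germline pathogenic variants in *MLH1*, *MSH2*, *MSH6* or *PMS2* cause
Lynch syndrome. Multigene panel testing frequently returns VUS, leaving
carriers without actionable risk information. This package implements, as
a tested and reusable pipeline, the tumor- and tissue-based lines of
evidence that discriminate a true germline mechanism from sporadic
mimics, and folds them into a five-tier classification:

1. **NGS-derived MSI/dMMR status** — six features (four MSI-tool score
   slots, somatic indel count, and the combined exposure of the
   MMR-deficiency indel signatures ID2+ID7 from a non-negative
   least-squares refit) are each thresholded; a tumor with **≥ 3 of 6**
   positive features is MSI-H/dMMR.
2. **Somatic second hit** — tumor/normal calls are consensus-filtered
   (PASS by both callers, depth ≥ 50 in both samples, VAF ≥ 10%,
   on-panel); LOH is called from germline-heterozygous markers by a
   VAF-shift test (|ΔVAF| ≥ 0.15 and Fisher exact p < 0.01, Bonferroni
   per gene). An inactivating event in the VUS gene is the Knudson
   second hit; two events in another gene indicate a sporadic
   "double somatic" mechanism.
3. **IHC concordance** — expected loss patterns follow heterodimer
   biology: MLH1→MLH1/PMS2, MSH2→MSH2/MSH6, MSH6→solitary MSH6,
   PMS2→solitary PMS2 (patchy loss counts as loss).
4. **MLH1 promoter methylation** — positive at MethyLight PMR ≥ 10% or
   MS-HRM ≥ 5%; explains dMMR as a sporadic phenocopy.
5. **dMMR crypt/gland screening** — serial-section immunostaining of
   normal mucosa/endometrium; a deficient crypt or gland matching the
   VUS gene is strong pathogenic support (a negative screen is neutral).

Per-variant evidence combines on the odds scale,
`posterior_odds = prior/(1−prior) · LR_tumor · LR_seg`, and a calibrated
rule engine maps profiles to the five tiers
(B / LB / VUS / LP / P). A priority-ordered decision tree assigns each
tumor a molecular-mechanism label (VUS + second hit, double somatic,
MLH1-methylation phenocopy, pMMR, bystander). A synthetic-cohort
generator with ground-truth mechanisms makes every stage testable
end-to-end, and a Poisson sampling model gives closed-form and
Monte-Carlo detection probabilities for the crypt screening protocol
(twenty 4 µm sections per 80 µm block, slides 1/10/19 stained, up to
three blocks).

## Worked example

The package ships a frozen transcription of a 24-family, 42-carrier
cohort with 25 MMR VUS, 28 sequenced tumors and 18 normal-tissue
screens. Running

```sh
mmr-vclass summarize
```

prints

```
variants: 25 (class4 7 [28.0%], class1-2 3, class3 15)
carriers: 42 in 24 families; multiple tumors 16 [38.1%]
proband IHC concordance: 13 concordant [52.0%], 8 discordant, 4 no loss
tumors sequenced: 28; MSI-H/dMMR 25, of which with IHC loss 23 [92.0%]
IHC-concordant tumors: 15; with second hit 13 [86.7%]
LP-variant tumors: 9; MSI-H 8 [88.9%], second hit 7 [77.8%]
double-somatic carriers: 8
crypt/gland screening (test group): 12 screened, 11 evaluable, 3 found [27.3%]; LP evaluable 4, found 2 [50.0%]
```

Reading: the rule engine upgrades 7/25 VUS to likely pathogenic and
downgrades 3 to benign/likely benign; 25 of the 28 sequenced tumors are
MSI-H/dMMR by the additive rule; among the IHC-concordant tumors, 86.7%
carry a somatic second hit in the VUS gene — the signature of a true
germline mechanism — while 8 carriers' tumors are instead explained by
double-somatic inactivation of a different gene.

Other entry points:

```sh
mmr-vclass validate                 # fixture integrity + referential checks
mmr-vclass classify-variants        # per-variant five-tier classes
mmr-vclass classify-tumors          # per-tumor mechanism labels
mmr-vclass simulate --seed 1        # synthetic cohort, mechanism recovery
mmr-vclass crypt-sim --density 0.7 --area 1 --diameter 200 --reps 20000 --seed 2
```

The last command compares the closed-form detection probability of the
sectioning protocol with a seeded Monte-Carlo estimate:

```
{
  "closed_form": 0.503415,
  "monte_carlo": 0.5014,
  "mc_standard_error": 0.003536,
  "blocks": 3,
  "reps": 20000
}
```

From Python, the same stack is available as a library:

```python
from mmr_vclass import load_fixture_bundle
from mmr_vclass.pipeline import run_fixture_analysis

cohort = load_fixture_bundle("all")
results, summary = run_fixture_analysis(cohort)
print(summary.class_counts)           # {1: 1, 2: 2, 3: 15, 4: 7, 5: 0}
```

## Acceptance script

`scripts/acceptance.py` recomputes the cohort's headline aggregates from
scratch — it loads the fixture bundle, runs the five-tier rule engine,
the IHC-concordance rule, second-hit detection, the additive MSI
combination and the tumor-odds product, and writes one JSON object with
the recomputed quantities:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/mmr_vclass/core.py` — domain types, cohort validation
- `src/mmr_vclass/somatic.py` — consensus filter, LOH, second hits, TMB
- `src/mmr_vclass/msi.py` — signature refit, locus scorer, 3-of-6 rule
- `src/mmr_vclass/classify.py` — rule engine, mechanism tree, summaries
- `src/mmr_vclass/crypts.py` — sectioning schedule, detection model
- `src/mmr_vclass/synthetic.py` — ground-truth cohort generator
- `src/mmr_vclass/fixtures.py`, `fixtures/` — frozen cohort tables (TSV)
- `src/mmr_vclass/pipeline.py`, `cli.py` — drivers, reports, CLI

See `docs/methods.md` for the model details, calibration rationale and
known limitations.
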