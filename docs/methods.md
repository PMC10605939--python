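# Methods

This note documents the models and procedures implemented in
`mmr_vclass`, the parameters that matter, the choices made where the
design was genuinely open, and what the tests do and do not establish.

## Somatic call filtering and mutation burden

Raw tumor/normal records carry PASS flags from two independent callers
plus depths and alt counts for both samples. The consensus filter keeps
calls that are PASS by **both** callers, have depth ≥ `min_depth`
(default 50) in tumor *and* matched normal, tumor VAF ≥ `min_vaf`
(default 0.10, inclusive — "minimum of 10%" reads as ≥), and lie inside
the capture region. Tumor mutation burden is the filtered call count
divided by `target_megabases` (default 2.005, the footprint of the
297-gene hereditary CRC/EC panel this models). A zero-depth record that
claims PASS is logged and dropped rather than raised: such rows occur in
malformed exports and should not abort a batch.

## LOH calling

The study this reproduces delegated LOH to an external tool without
published parameters, so the test here is re-specified from first
principles. For each MMR gene, germline-heterozygous marker sites
(normal VAF in [0.30, 0.70]) are tested for an allelic shift in the
tumor. A gene is LOH when at least `min_informative_markers` (default 1)
sites show **both** an effect-size shift |tumorVAF − normalVAF| ≥ 0.15
and a two-sided Fisher exact test of tumor-vs-normal alt fraction
significant at α = 0.01 after Bonferroni correction over that gene's
markers. The effect-size gate prevents trivially significant sub-0.05
shifts at very high depth from being called LOH; the exact test prevents
chance shifts at low depth. Genes with no informative marker are
reported *untestable* (`None`), never "no LOH". The test is invariant
under relabeling ref/alt at a site (|ΔVAF| and the two-sided test are
label-symmetric).

## Somatic events, second hits, double somatics

Every filtered call in an MMR gene becomes a `single_mutation` event;
each LOH-flagged gene adds one `loh` event. The inactivating tier uses a
curated ACMG class (≥ 4) when present; otherwise truncating consequences
(nonsense, frameshift, splice) count and missense/synonymous do not —
this consequence fallback keeps the synthetic path self-contained
without an annotation database. Events are counted, never deduplicated
(a gene can legitimately carry "2× mut."). A **second hit** is ≥ 1
inactivating event in the gene carrying the germline variant; a
**double somatic** gene has ≥ 2 inactivating events (LOH counts once).

## MSI-H/dMMR by additive feature combination

Six features vote: four MSI-tool score slots (external scores are
accepted as precomputed values; one slot can be filled by the bespoke
per-locus scorer below), the somatic indel count, and the combined
ID2+ID7 signature exposure. Each feature is thresholded; a tumor with
**≥ 3 of 6** positive features is MSI-H/dMMR. Absent features count as
negative and never shrink the denominator: the rule is defined over a
fixed panel. The shipped cutoffs (0.2 for the four score slots, 10 for
indel count, 0.2 for ID2+ID7 exposure) are **not literature values** —
the source benchmark's cutoffs are not published alongside the rule — so
they are configuration, calibrated once against the synthetic generator
and then frozen.

*Signature refit.* The tumor indel catalog (83-channel small-indel
layout) is normalized to channel frequencies and refit onto a
channels × signatures matrix by non-negative least squares
(`scipy.optimize.nnls`); exposures are renormalized to sum to one.
Fitting frequencies rather than counts makes the exposure vector
invariant to mutation load. The packaged signature matrix is an
explicitly **synthetic stand-in** whose ID2/ID7 columns concentrate on
single-base deletions at homopolymer runs; real analyses should supply a
real reference matrix.

*Per-locus instability scorer.* A microsatellite locus with ≥ 20 reads
in both samples is unstable when the tumor's modal repeat length differs
from the normal's, or more than 20% of tumor reads fall outside the
normal's modal length. The score is the unstable fraction of assessable
loci; zero assessable loci yields an absent score. Modal ties break
toward the shorter repeat, deterministically.

## Five-tier rule engine

Per-variant evidence combines on the odds scale:

    posterior_odds = prior/(1 − prior) · LR_tumor · LR_seg

with absent terms neutral (= 1). The mapping to tiers is deliberately
*not* a pure posterior threshold, because curated classifications are
not a function of the posterior alone; the shipped gates are calibrated
against the packaged 25-variant evidence table and are configuration
(`RuleSet`, YAML-loadable):

- **Class 5 (P)** — posterior ≥ 0.99 *and* corroborating functional
  evidence. The posterior alone never reaches "pathogenic".
- **Class 4 (LP)** — posterior ≥ 0.95 with the variant observed in ≥ 2
  families; *or* a predicted loss-of-function variant (NMD expected)
  with ≥ 1 concordant dMMR tumor; *or* splice-prediction support
  (SpliceAI delta > 0.2) together with supportive tumor odds (≥ 1).
- **Class 1 (B)** — in-silico prior of 0 with zero tumor odds in an
  allele that is not rare (population frequency ≥ 1/50 000).
- **Class 2 (LB)** — posterior < 0.001 together with segregation
  evidence against pathogenicity (LR < 1); *or* demonstrated alternate
  mechanism ("bystander": in every dMMR tumor of the variant's carriers
  the IHC is discordant with this gene, the gene carries no somatic
  hit, and a co-carried variant's gene both matches the IHC loss and
  harbors a second hit).
- **Class 3 (VUS)** — everything else, including wholly absent evidence.

Two asymmetries are intentional. Benign assignment requires
*affirmative* benign evidence, not merely a low posterior: several
curated class-3 variants have posteriors below 0.001, and a low prior
with weak tumor odds is not the same observation as segregation against
the phenotype. And a "strong segregation" flag (combined LR > 18.7 in
≥ 2 families) is computed but not itself a gate, since no packaged
variant reaches it. The engine is monotone: increasing the tumor LR
(all else fixed) never lowers the class.

Population rarity is tri-state: a printed frequency of 0 means
observed-zero (rare); a missing value means unknown (flag absent), and
unknown rarity never counts toward any gate.

The per-tumor likelihood-ratio table (`TumorLRTable`) is calibration,
not derivation: the source tables behind the printed per-tumor odds are
inconsistent across entries (identical contexts print different LRs), so
curated combined odds are taken as given when present and the table is
used only for the synthetic path.

## Per-tumor mechanism decision tree

Priority order, first match wins:

1. **MLH1-methylation phenocopy** — methylation positive and MLH1 among
   the lost proteins, regardless of the sequencing MSI call (the one
   packaged phenocopy is MSS 0/6 by sequencing yet clearly methylated).
2. **VUS + second hit** — MSI-H, second hit present, and IHC concordant
   *or* showing no loss (a false-negative IHC must not veto a sequencing-
   confirmed second hit).
3. **Double somatic** — MSI-H and a different gene doubly hit whose
   expected dimer pattern equals the observed loss. When 2 and 3 both
   fire for different genes the IHC-pattern match wins; when the doubly
   hit gene is the VUS gene itself, rule 2 wins with an ambiguity flag
   (the second hit and a somatic-only mechanism are then
   indistinguishable).
4. **VUS only** — MSI-H, concordant, no second hit.
5. **pMMR** — not MSI-H.
6. **Bystander** — a co-carried variant whose gene is neither concordant
   with the loss pattern nor somatically hit.

A dMMR tumor matching no rule returns no label plus a diagnostic string,
forcing review rather than silently defaulting.

## Crypt/gland screening model

The staining schedule places section *i* of block *b* at depth
`(b·sections_per_block + i − 1)·thickness`; defaults (20 sections of
4 µm, slides 1/10/19, ≤ 3 blocks) give nine stained planes over 240 µm.
Crypt centers follow a Poisson process with `crypt_density` per mm² over
`examined_area`; a crypt of diameter *d* is detected when a stained
plane passes within *d*/2 of its center. Detection probability is
`1 − exp(−λ)` with `λ = density · area · coverage_fraction`, where the
coverage fraction is the measure of the union of ±*d*/2 bands around the
stained depths, clipped to the sampled thickness. A seeded Monte-Carlo
simulation of the same geometry is the independent check (agreement
within 3 standard errors is a test invariant). Crypt density and
diameter have **no established values** and are required configuration —
the model intentionally refuses to invent biological constants. The
control-slide re-stain (the section after a hit, stained for the
unaffected protein) is a confirmation step, not an extra detection
opportunity, and is not modeled as one.

## Synthetic cohort generator

The generator emulates the study design: five mechanisms (Lynch-true
with second hit, sporadic double somatic, MLH1-methylated phenocopy,
pMMR sporadic, benign bystander), 50 carriers each by default. Signal
parameters mirror the sequencing design modeled here: ~906× tumor /
~154× normal mean depth on a 2.005 Mb capture; planted driver VAFs
0.25–0.45; LOH markers shifted from VAF 0.5 to 0.85; the second-hit
kind an even LOH/mutation split; an 8% IHC false-negative rate applied
to Lynch-true tumors (motivating the no-loss branch of rule 2); dMMR
indel catalogs drawn ID2/ID7-dominant (~60 indels) versus a flat
background (~3). Planted decoys — one-caller-only, low-VAF, off-panel —
must be removed by the consensus filter, which the tests assert.

All randomness flows from one seed through `SeedSequence` children keyed
by (seed, tumor index, stream), so any sub-stage regenerates in
isolation and the per-feature noise flips are *coupled* across noise
levels: raising `msi_feature_noise` can only grow the flip set, making
recovery monotone along a noise ladder by construction.

What a green end-to-end test establishes: the full computational path
(filter → LOH → events → refit → locus score → 3-of-6 → decision tree)
recovers ≥ 90% of planted mechanisms under the stated-world defaults,
and every methylated phenocopy is labeled as such. What it does not
establish: performance on real panels — the generator has no alignment
artifacts, FFPE damage, subclonality, purity variation, or realistic
microsatellite error profiles, and methylated tumors always show
MLH1/PMS2 loss (IHC noise is modeled only for the germline scenario).

## Numerical and degenerate-input choices

- VAF and feature thresholds are inclusive (≥); the MSI rule boundary
  is exact on both sides of 3/6.
- Fisher p-values are Bonferroni-corrected within gene and capped at 1.
- NNLS exposures renormalize only when the raw solution is non-zero; a
  zero catalog warns and returns all-zero exposures.
- `combine_tumor_lr([])` is 1.0 (the neutral element); non-positive LRs
  are hard errors.
- Curated records may carry a combined tumor LR of exactly 0 (a printed
  benign odds); the combination operator itself still rejects 0.
- Genomic positions are 1-based (VCF convention); interval checks are
  inclusive at both ends.
- "Not tested" is everywhere distinct from "negative" (`None` vs
  `False`); untestable outcomes propagate as absent, never as negative.

## Known limitations

- The five-tier gates are calibrated to one curated cohort; they are a
  faithful executable account of that cohort's classifications, not a
  re-derivation of the underlying quantitative framework, whose
  per-tumor LR sources are not fully published.
- The loss-of-function (NMD) flag and functional-evidence field are
  curated inputs, not predictions.
- The locus instability scorer is a deliberately simple stand-in for the
  four published MSI callers, which are out of scope; their score slots
  accept real values.
- Exactly one packaged signature matrix is synthetic (see above); no
  single-base-substitution signatures are modeled.
- The crypt detection model is two-dimensional in depth only; it ignores
  lateral sectioning geometry and crypt clustering.
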