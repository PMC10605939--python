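"""ACMG/InSiGHT evidence integration and per-tumor mechanism calls.

Two complementary classifications are produced:

* a five-tier class per germline variant (benign ... pathogenic), from a
  Bayesian combination of an in-silico prior with tumor-characteristic and
  co-segregation likelihood ratios, plus combinatorial criteria
  (predicted loss of function, splice-prediction support, alternate
  molecular mechanism);

* a molecular-mechanism label per (tumor, variant) pair -- germline variant
  plus somatic second hit, sporadic double-somatic inactivation, MLH1
  promoter-methylation phenocopy, MMR-proficient, or bystander variant --
  from a priority-ordered decision tree over MSI status, IHC pattern,
  methylation and the somatic event multiset.

The quantitative cut-points of the rule engine are configuration, not
universal constants: the shipped defaults are calibrated against a curated
evidence table (see the fixtures) and documented as such.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    EXPECTED_IHC_LOSS,
    MMR_GENES,
    Cohort,
    CryptScreenRecord,
    EvidenceRecord,
    FunctionalEvidence,
    GermlineVariant,
    IHCPattern,
    MethylationResult,
    ScreenOutcome,
    Tissue,
    TumorAssessment,
)
from .msi import additive_combination
from .somatic import SecondHit, detect_double_somatic, detect_second_hit


class Concordance(str, enum.Enum):
    concordant = "concordant"
    discordant = "discordant"
    no_loss = "no_loss"


def ihc_concordance(vus_gene: str, ihc: Optional[IHCPattern]) -> Optional[Concordance]:
    """Compare an IHC loss pattern with the gene carrying the variant.

    The expected pattern follows heterodimer biology: MLH1 loss
    destabilizes PMS2 (and vice versa is not true), MSH2 loss destabilizes
    MSH6, while MSH6 and PMS2 defects give solitary loss.  Patchy loss
    counts as loss.  Returns ``None`` when IHC was not done (excluded from
    concordance denominators).
    """
    if ihc is None:
        return None
    if ihc.is_normal:
        return Concordance.no_loss
    if ihc.lost_proteins == EXPECTED_IHC_LOSS[vus_gene]:
        return Concordance.concordant
    return Concordance.discordant


def mlh1_methylation_call(
    m: MethylationResult, pmr_cutoff: float = 10.0, hrm_cutoff: float = 5.0
) -> bool:
    """MLH1 promoter methylation positivity.

    Positive when the MethyLight percentage of methylated reference is
    >= 10% or the MS-HRM estimate is >= 5%; either assay suffices.
    """
    if m.methylight_pmr is not None and m.methylight_pmr >= pmr_cutoff:
        return True
    if m.mshrm_percent is not None and m.mshrm_percent >= hrm_cutoff:
        return True
    return False


def combine_tumor_lr(per_tumor_lrs: Sequence[float]) -> float:
    """Multiply per-tumor likelihood ratios into combined odds.

    Independent tumors contribute multiplicatively on the odds scale; the
    empty product is 1 (neutral evidence).
    """
    combined = 1.0
    for lr in per_tumor_lrs:
        if lr <= 0:
            raise ValueError(f"likelihood ratios must be positive, got {lr}")
        combined *= lr
    return combined


@dataclass
class TumorLRTable:
    """Per-tumor likelihood ratio of variant pathogenicity by context.

    Keyed by (tissue, MSI-high flag, concordance).  Cell values are
    calibration constants supplied by configuration; the shipped defaults
    reproduce the odds printed for single-tumor entries in the curated
    evidence table and are not derived from first principles.
    """

    cells: dict = field(default_factory=dict)
    default_lr: float = 1.0

    @classmethod
    def default(cls) -> "TumorLRTable":
        return cls(
            cells={
                (Tissue.CRC, True, Concordance.concordant): 6.52,
                (Tissue.EC, True, Concordance.concordant): 0.41,
                (Tissue.CRC, False, Concordance.no_loss): 0.11,
                (Tissue.EC, False, Concordance.no_loss): 0.11,
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "TumorLRTable":
        """Load cells from YAML: a list of {tissue, msi_high, concordance, lr}."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cells = {}
        for row in data.get("cells", []):
            key = (
                Tissue(row["tissue"]),
                bool(row["msi_high"]),
                Concordance(row["concordance"]) if row.get("concordance") else None,
            )
            cells[key] = float(row["lr"])
        return cls(cells=cells, default_lr=float(data.get("default_lr", 1.0)))

    def lookup(self, tissue: Tissue, msi_high: bool, concordance: Optional[Concordance]) -> float:
        lr = self.cells.get((tissue, msi_high, concordance), self.default_lr)
        if lr <= 0:
            raise ValueError("tumor LR table cells must be positive")
        return lr


@dataclass
class RuleSet:
    """Cut-points and gates of the five-tier rule engine (configuration)."""

    posterior_pathogenic: float = 0.99
    posterior_likely_pathogenic: float = 0.95
    lp_min_families: int = 2
    spliceai_delta_cutoff: float = 0.2
    splice_lp_min_tumor_lr: float = 1.0
    posterior_benign_support: float = 0.001
    rarity_cutoff: float = 1.0 / 50_000
    strong_segregation_lr: float = 18.7
    strong_segregation_min_families: int = 2

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleSet":
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvidenceProfile:
    """Per-variant ledger of the integrated evidence items."""

    variant_id: str
    gene: str = ""
    rare_in_population: Optional[bool] = None
    rarity_cutoff: float = 1.0 / 50_000
    prior_probability: Optional[float] = None
    tumor_lr_combined: Optional[float] = None
    seg_lr_combined: Optional[float] = None
    seg_family_count: int = 1
    spliceai_pathogenic: bool = False
    functional_evidence: FunctionalEvidence = FunctionalEvidence.none
    nmd_predicted: bool = False
    concordant_tumor_count: int = 0
    discordant_tumor_count: int = 0
    #: BP2-style alternate mechanism: every dMMR tumor of this variant's
    #: carriers is explained by a co-carried variant in another gene
    bystander_evidence: bool = False
    strong_segregation: bool = False
    posterior_probability: Optional[float] = None


class TierLabel(str, enum.Enum):
    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"


_TIER_LABELS = {1: TierLabel.B, 2: TierLabel.LB, 3: TierLabel.VUS, 4: TierLabel.LP, 5: TierLabel.P}


@dataclass(frozen=True)
class FiveTierClass:
    klass: int
    label: TierLabel = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.klass not in _TIER_LABELS:
            raise ValueError(f"class must be 1..5, got {self.klass}")
        expected = _TIER_LABELS[self.klass]
        if self.label is None:
            object.__setattr__(self, "label", expected)
        elif TierLabel(self.label) is not expected:
            raise ValueError(f"label {self.label} does not match class {self.klass}")


def _posterior(profile: EvidenceProfile) -> Optional[float]:
    prior = profile.prior_probability
    if prior is None:
        return None
    if prior >= 1.0:
        return 1.0
    odds = prior / (1.0 - prior)
    odds *= profile.tumor_lr_combined if profile.tumor_lr_combined is not None else 1.0
    odds *= profile.seg_lr_combined if profile.seg_lr_combined is not None else 1.0
    return odds / (1.0 + odds)


def build_evidence_profile(
    variant: GermlineVariant,
    cohort: Optional[Cohort] = None,
    lr_table: Optional[TumorLRTable] = None,
    rules: Optional[RuleSet] = None,
) -> EvidenceProfile:
    """Assemble the evidence ledger for one variant.

    Population rarity, in-silico prior, splice prediction and functional
    evidence come from the variant record; combined tumor odds and
    segregation come from the cohort's curated evidence table when present,
    otherwise the tumor odds are rebuilt from the variant's sequenced
    tumors via ``lr_table``.  Absent components stay absent -- they are
    neutral, not negative.
    """
    rules = rules or RuleSet()
    record = cohort.evidence.get(variant.variant_id) if cohort else None
    record = record or EvidenceRecord(variant_id=variant.variant_id)

    rare: Optional[bool] = None
    if variant.gnomad_af is not None:
        rare = variant.gnomad_af < rules.rarity_cutoff

    tumor_lr = record.tumor_lr_combined
    assessments = _assessments_for(cohort, variant.variant_id) if cohort else []
    if tumor_lr is None and lr_table is not None and assessments:
        lrs = []
        for res in assessments:
            lrs.append(lr_table.lookup(res.tumor.tissue, res.msi_high, res.concordance))
        tumor_lr = combine_tumor_lr(lrs)

    seg_lr = record.seg_lr_combined
    profile = EvidenceProfile(
        variant_id=variant.variant_id,
        gene=variant.gene,
        rare_in_population=rare,
        rarity_cutoff=rules.rarity_cutoff,
        prior_probability=variant.prior_probability,
        tumor_lr_combined=tumor_lr,
        seg_lr_combined=seg_lr,
        seg_family_count=record.n_families,
        spliceai_pathogenic=(
            variant.spliceai_delta is not None
            and variant.spliceai_delta > rules.spliceai_delta_cutoff
        ),
        functional_evidence=variant.functional_evidence,
        nmd_predicted=bool(variant.nmd_predicted),
        concordant_tumor_count=record.n_tumors_concordant,
        discordant_tumor_count=record.n_tumors_discordant,
        bystander_evidence=_bystander_evidence(cohort, variant) if cohort else False,
        strong_segregation=(
            seg_lr is not None
            and seg_lr > rules.strong_segregation_lr
            and record.n_families >= rules.strong_segregation_min_families
        ),
    )
    profile.posterior_probability = _posterior(profile)
    return profile


@dataclass
class _TumorDeterminations:
    tumor: object
    concordance: Optional[Concordance]
    msi_high: bool
    second_hit: SecondHit
    double_somatic: list


def _assessments_for(cohort: Cohort, variant_id: str) -> list[_TumorDeterminations]:
    out = []
    for a in cohort.tumor_assessments:
        if a.variant_id != variant_id:
            continue
        gene = cohort.variants[variant_id].gene
        msi_high = (
            a.msi_positive_count is not None and a.msi_positive_count >= 3
        )
        out.append(
            _TumorDeterminations(
                tumor=a.tumor,
                concordance=ihc_concordance(gene, a.tumor.ihc),
                msi_high=msi_high,
                second_hit=detect_second_hit(gene, a.tumor.events),
                double_somatic=detect_double_somatic(a.tumor.events),
            )
        )
    return out


def _bystander_evidence(cohort: Cohort, variant: GermlineVariant) -> bool:
    """Alternate-mechanism (bystander) evidence for a co-carried variant.

    True when the variant is co-carried with another variant and, in every
    sequenced dMMR tumor of its carriers, the IHC pattern is discordant
    with this variant's gene, no somatic hit falls in this gene, and a
    co-carried variant's gene both matches the IHC loss and harbors a
    somatic second hit.
    """
    determinations = _assessments_for(cohort, variant.variant_id)
    dmmr = [d for d in determinations if d.msi_high]
    if not dmmr:
        return False
    for det in dmmr:
        if det.concordance is not Concordance.discordant or det.second_hit.present:
            return False
        carrier = cohort.carriers.get(det.tumor.carrier_id)
        if carrier is None:
            return False
        explained = False
        for other_id in carrier.carried_variants:
            if other_id == variant.variant_id:
                continue
            other_gene = cohort.variants[other_id].gene
            if (
                ihc_concordance(other_gene, det.tumor.ihc) is Concordance.concordant
                and detect_second_hit(other_gene, det.tumor.events).present
            ):
                explained = True
        if not explained:
            return False
    return True


def classify_acmg_insight(
    profile: EvidenceProfile, rules: Optional[RuleSet] = None
) -> FiveTierClass:
    """Map an evidence profile to the five-tier class.

    Gates, in priority order:

    5  posterior >= 0.99 *and* corroborating functional evidence -- the
       posterior alone never reaches "pathogenic";
    4  posterior >= 0.95 with the variant observed in >= 2 families, or a
       predicted loss-of-function variant with >= 1 concordant dMMR tumor,
       or splice-prediction support (delta > 0.2) with supportive tumor
       odds;
    1  in-silico prior of zero with zero tumor odds in a non-rare allele;
    2  posterior below the benign-support bound together with segregation
       evidence against pathogenicity, or demonstrated alternate mechanism
       (bystander);
    3  everything else, including wholly absent evidence.
    """
    rules = rules or RuleSet()
    post = profile.posterior_probability

    if (
        post is not None
        and post >= rules.posterior_pathogenic
        and profile.functional_evidence is FunctionalEvidence.supports_pathogenic
    ):
        return FiveTierClass(5)
    if (
        post is not None
        and post >= rules.posterior_likely_pathogenic
        and profile.seg_family_count >= rules.lp_min_families
    ):
        return FiveTierClass(4)
    if profile.nmd_predicted and profile.concordant_tumor_count >= 1:
        return FiveTierClass(4)
    if (
        profile.spliceai_pathogenic
        and profile.tumor_lr_combined is not None
        and profile.tumor_lr_combined >= rules.splice_lp_min_tumor_lr
    ):
        return FiveTierClass(4)
    if (
        profile.prior_probability == 0.0
        and profile.tumor_lr_combined == 0.0
        and profile.rare_in_population is False
    ):
        return FiveTierClass(1)
    if (
        post is not None
        and post < rules.posterior_benign_support
        and profile.seg_lr_combined is not None
        and profile.seg_lr_combined < 1.0
    ) or profile.bystander_evidence:
        return FiveTierClass(2)
    return FiveTierClass(3)


class MechanismLabel(str, enum.Enum):
    dmmr_vus_plus_second_hit = "dmmr_vus_plus_second_hit"
    dmmr_vus_only = "dmmr_vus_only"
    dmmr_double_somatic = "dmmr_double_somatic"
    dmmr_mlh1_methylation = "dmmr_mlh1_methylation"
    pmmr = "pmmr"
    vus_benign_bystander = "vus_benign_bystander"


@dataclass
class FinalTumorLabel:
    label: Optional[MechanismLabel]
    implicated_gene: Optional[str] = None
    ambiguity_flag: bool = False
    diagnostic: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label in (
            MechanismLabel.dmmr_vus_plus_second_hit,
            MechanismLabel.dmmr_vus_only,
            MechanismLabel.dmmr_double_somatic,
            MechanismLabel.dmmr_mlh1_methylation,
        ) and self.implicated_gene is None:
            raise ValueError(f"{self.label}: implicated_gene required for dMMR labels")


def final_tumor_classification(
    vus_gene: str,
    ihc: Optional[IHCPattern],
    second_hit: SecondHit,
    double_somatic_genes: Sequence[str],
    msi_high: bool,
    concordance: Optional[Concordance],
    methylation_positive: Optional[bool] = None,
    co_carried_genes: Sequence[str] = (),
) -> FinalTumorLabel:
    """Priority-ordered decision tree assigning the tumor's dMMR mechanism.

    1. MLH1 promoter methylation with MLH1 protein loss explains dMMR
       regardless of the sequencing-derived MSI call (sporadic phenocopy).
    2. MSI-H with a second hit in the VUS gene and IHC that is concordant
       or shows no loss (false-negative IHC is tolerated): germline variant
       plus second hit.
    3. MSI-H with a different gene doubly hit whose expected IHC pattern
       matches the observed loss: sporadic double somatic.  When rules 2
       and 3 both fire for different genes, the IHC-pattern match wins;
       when the doubly-hit gene is the VUS gene itself, rule 2 wins with
       an ambiguity flag.
    4. MSI-H, concordant IHC, no second hit: the variant remains the best
       candidate mechanism.
    5. Not MSI-H: MMR-proficient.
    6. A co-carried variant whose gene is neither concordant with the IHC
       loss nor somatically hit is a benign bystander to this tumor.
    """
    if methylation_positive and ihc is not None and "MLH1" in ihc.lost_proteins:
        return FinalTumorLabel(MechanismLabel.dmmr_mlh1_methylation, implicated_gene="MLH1")

    rule2 = (
        msi_high
        and second_hit.present
        and concordance in (Concordance.concordant, Concordance.no_loss)
    )
    rule3_genes = []
    if msi_high and ihc is not None and not ihc.is_normal:
        rule3_genes = [
            g
            for g in double_somatic_genes
            if g != vus_gene and EXPECTED_IHC_LOSS[g] == ihc.lost_proteins
        ]

    if rule3_genes and not rule2:
        return FinalTumorLabel(MechanismLabel.dmmr_double_somatic, implicated_gene=rule3_genes[0])
    if rule2 and rule3_genes:
        # both mechanisms are supported for different genes: the gene whose
        # expected pattern matches the observed IHC loss wins
        return FinalTumorLabel(
            MechanismLabel.dmmr_double_somatic,
            implicated_gene=rule3_genes[0],
            ambiguity_flag=True,
        )
    if rule2:
        return FinalTumorLabel(
            MechanismLabel.dmmr_vus_plus_second_hit,
            implicated_gene=vus_gene,
            ambiguity_flag=vus_gene in double_somatic_genes,
        )
    if msi_high and concordance is Concordance.concordant and not second_hit.present:
        return FinalTumorLabel(MechanismLabel.dmmr_vus_only, implicated_gene=vus_gene)
    if not msi_high:
        return FinalTumorLabel(MechanismLabel.pmmr)
    if co_carried_genes and concordance is Concordance.discordant and not second_hit.present:
        return FinalTumorLabel(MechanismLabel.vus_benign_bystander)
    return FinalTumorLabel(
        None,
        diagnostic=(
            f"dMMR tumor with no mechanism: gene={vus_gene} "
            f"concordance={concordance} second_hit={second_hit.present} "
            f"double_somatic={list(double_somatic_genes)}"
        ),
    )


@dataclass
class CryptEvidence:
    supports_pathogenic: bool
    rationale: str
    klass: FiveTierClass


def integrate_crypt_evidence(
    klass: FiveTierClass, screen: CryptScreenRecord, vus_gene: str
) -> CryptEvidence:
    """Fold a normal-tissue screening outcome into a variant's report.

    A dMMR crypt/gland whose deficient protein matches the expected loss
    pattern of the VUS gene is strong supporting evidence for
    pathogenicity.  A negative, failed or absent screen is neutral: tissue
    may simply have been insufficient, so the class is never downgraded.
    """
    if screen.outcome is ScreenOutcome.found and (
        screen.deficient_protein in EXPECTED_IHC_LOSS[vus_gene]
    ):
        return CryptEvidence(
            supports_pathogenic=True,
            rationale=(
                f"dMMR crypt/gland with {screen.deficient_protein} loss is "
                f"concordant with a germline {vus_gene} defect"
            ),
            klass=klass,
        )
    if screen.outcome is ScreenOutcome.found:
        return CryptEvidence(
            supports_pathogenic=False,
            rationale=(
                f"dMMR crypt/gland ({screen.deficient_protein} loss) does not "
                f"match the expected pattern for {vus_gene}"
            ),
            klass=klass,
        )
    return CryptEvidence(
        supports_pathogenic=False,
        rationale=f"screen outcome {screen.outcome.value}: neutral, class unchanged",
        klass=klass,
    )


# ---------------------------------------------------------------------------
# cohort-level analysis


@dataclass
class AssessmentResult:
    assessment: TumorAssessment
    concordance: Optional[Concordance]
    msi_high: bool
    second_hit: SecondHit
    double_somatic: list
    final: FinalTumorLabel
    #: first assessment row for this tumor (distinct-tumor statistics)
    is_primary: bool = True


@dataclass
class CohortResults:
    profiles: dict = field(default_factory=dict)  # variant_id -> EvidenceProfile
    variant_classes: dict = field(default_factory=dict)  # variant_id -> FiveTierClass
    assessments: list = field(default_factory=list)  # list[AssessmentResult]


def analyze_cohort(
    cohort: Cohort,
    rules: Optional[RuleSet] = None,
    lr_table: Optional[TumorLRTable] = None,
) -> CohortResults:
    """Run variant classification and tumor mechanism calls over a cohort."""
    rules = rules or RuleSet()
    results = CohortResults()

    for vid, variant in cohort.variants.items():
        profile = build_evidence_profile(variant, cohort, lr_table=lr_table, rules=rules)
        results.profiles[vid] = profile
        results.variant_classes[vid] = classify_acmg_insight(profile, rules)

    seen_tumors: set[str] = set()
    for a in cohort.tumor_assessments:
        gene = cohort.variants[a.variant_id].gene
        concordance = ihc_concordance(gene, a.tumor.ihc)
        if a.msi_positive_count is not None:
            msi_high = additive_combination(a.msi_positive_count)[0] == "MSI-H/dMMR"
        elif a.tumor.msi_features is not None:
            msi_high = additive_combination(a.tumor.msi_features)[0] == "MSI-H/dMMR"
        else:
            msi_high = False
        second_hit = detect_second_hit(gene, a.tumor.events)
        double = detect_double_somatic(a.tumor.events)
        if a.tumor.mlh1_methylation is not None:
            methylated: Optional[bool] = mlh1_methylation_call(a.tumor.mlh1_methylation)
        else:
            methylated = a.tumor.mlh1_methylation_positive
        carrier = cohort.carriers.get(a.tumor.carrier_id)
        co_carried = []
        if carrier is not None:
            co_carried = [
                cohort.variants[v].gene
                for v in carrier.carried_variants
                if v != a.variant_id and v in cohort.variants
            ]
        final = final_tumor_classification(
            gene,
            a.tumor.ihc,
            second_hit,
            double,
            msi_high,
            concordance,
            methylation_positive=methylated,
            co_carried_genes=co_carried,
        )
        results.assessments.append(
            AssessmentResult(
                assessment=a,
                concordance=concordance,
                msi_high=msi_high,
                second_hit=second_hit,
                double_somatic=double,
                final=final,
                is_primary=a.tumor.tumor_id not in seen_tumors,
            )
        )
        seen_tumors.add(a.tumor.tumor_id)
    return results


@dataclass
class CohortSummary:
    """Aggregate counts of the cohort analysis (headline fractions)."""

    n_variants: int = 0
    class_counts: dict = field(default_factory=lambda: {k: 0 for k in range(1, 6)})
    n_carriers: int = 0
    n_families: int = 0
    n_multi_tumor_carriers: int = 0
    proband_concordant: int = 0
    proband_discordant: int = 0
    proband_no_loss: int = 0
    n_tumors_sequenced: int = 0
    n_msi_high: int = 0
    n_msi_high_with_ihc_loss: int = 0
    n_ihc_concordant_tumors: int = 0
    n_concordant_with_second_hit: int = 0
    n_lp_tumors: int = 0
    n_lp_msi_high: int = 0
    n_lp_second_hit: int = 0
    n_double_somatic_carriers: int = 0
    n_test_screens: int = 0
    n_screens_evaluable: int = 0
    n_screens_found: int = 0
    n_lp_screens_evaluable: int = 0
    n_lp_screens_found: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["class_counts"] = {str(k): v for k, v in self.class_counts.items()}
        return d


def cohort_summary(cohort: Cohort, results: CohortResults) -> CohortSummary:
    """Recount every headline fraction from the per-entity results."""
    s = CohortSummary()
    s.n_variants = len(cohort.variants)
    s.n_carriers = len(cohort.carriers)
    s.n_families = len(cohort.families)
    for klass in results.variant_classes.values():
        s.class_counts[klass.klass] += 1

    s.n_multi_tumor_carriers = sum(
        1 for n in cohort.carrier_tumor_counts().values() if n >= 2
    )

    for vid, record in cohort.evidence.items():
        conc = ihc_concordance(cohort.variants[vid].gene, record.case_ihc)
        if conc is Concordance.concordant:
            s.proband_concordant += 1
        elif conc is Concordance.discordant:
            s.proband_discordant += 1
        elif conc is Concordance.no_loss:
            s.proband_no_loss += 1

    lp_variants = {vid for vid, k in results.variant_classes.items() if k.klass == 4}
    double_somatic_carriers = set()
    for res in results.assessments:
        if res.final.label is MechanismLabel.dmmr_double_somatic:
            double_somatic_carriers.add(res.assessment.tumor.carrier_id)
        if res.assessment.variant_id in lp_variants:
            s.n_lp_tumors += 1
            s.n_lp_msi_high += res.msi_high
            s.n_lp_second_hit += res.second_hit.present
        if not res.is_primary:
            continue
        s.n_tumors_sequenced += 1
        if res.msi_high:
            s.n_msi_high += 1
            ihc = res.assessment.tumor.ihc
            if ihc is not None and not ihc.is_normal:
                s.n_msi_high_with_ihc_loss += 1
        if res.concordance is Concordance.concordant:
            s.n_ihc_concordant_tumors += 1
            s.n_concordant_with_second_hit += res.second_hit.present
    s.n_double_somatic_carriers = len(double_somatic_carriers)

    for screen in cohort.crypt_screens:
        if getattr(screen, "group", "test").startswith("reference"):
            continue
        s.n_test_screens += 1
        evaluable = screen.outcome in (ScreenOutcome.found, ScreenOutcome.not_found)
        found = screen.outcome is ScreenOutcome.found
        s.n_screens_evaluable += evaluable
        s.n_screens_found += found
        vid = getattr(screen, "variant_id", None)
        if vid is not None and vid in lp_variants:
            s.n_lp_screens_evaluable += evaluable
            s.n_lp_screens_found += found
    return s
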