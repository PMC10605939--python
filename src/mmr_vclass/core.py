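"""Core domain model for mismatch-repair (MMR) variant interpretation cohorts.

The package revolves around four MMR genes (MLH1, MSH2, MSH6, PMS2) whose
germline inactivation causes Lynch syndrome.  A cohort is a graph of
families, carriers, germline variants, tumors (with their molecular
dossiers) and normal-tissue screening records.  Everything downstream --
somatic second-hit detection, MSI calling, the ACMG/InSiGHT rule engine --
consumes these types.

Conventions
-----------
* Genomic positions are 1-based (VCF style); any interval arithmetic is done
  0-based half-open internally with conversion at the boundary.
* "Not tested" is distinct from "negative": tri-state fields use
  ``None`` for not-tested/unknown and real values otherwise.
* TSV serialization uses ``NT`` or the empty string as the absent sentinel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

#: IHC loss pattern expected when a given MMR gene is inactivated.  MLH1 and
#: MSH2 are the obligate partners of the MutL-alpha (MLH1/PMS2) and
#: MutS-alpha (MSH2/MSH6) heterodimers: losing them destabilizes the partner
#: protein as well, whereas PMS2 and MSH6 loss leaves the partner intact.
EXPECTED_IHC_LOSS = {
    "MLH1": frozenset({"MLH1", "PMS2"}),
    "MSH2": frozenset({"MSH2", "MSH6"}),
    "MSH6": frozenset({"MSH6"}),
    "PMS2": frozenset({"PMS2"}),
}


class VariantType(str, enum.Enum):
    missense = "missense"
    inframe_deletion = "inframe_deletion"
    frameshift = "frameshift"
    splice = "splice"
    exon_duplication = "exon_duplication"
    utr5 = "utr5"
    utr3 = "utr3"


class Consequence(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    insertion = "insertion"
    deletion = "deletion"
    frameshift = "frameshift"
    splice = "splice"
    synonymous = "synonymous"
    other = "other"


#: Consequences taken as gene-inactivating when no curated ACMG tier is
#: available for a somatic call.
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.nonsense, Consequence.frameshift, Consequence.splice}
)


class FunctionalEvidence(str, enum.Enum):
    none = "none"
    supports_pathogenic = "supports_pathogenic"
    supports_benign = "supports_benign"


class Tissue(str, enum.Enum):
    CRC = "CRC"
    EC = "EC"
    other = "other"


class EventKind(str, enum.Enum):
    single_mutation = "single_mutation"
    loh = "loh"


class BrafStatus(str, enum.Enum):
    wildtype = "wildtype"
    mutant = "mutant"
    not_tested = "not_tested"


@dataclass
class GermlineVariant:
    """One germline variant of uncertain significance (VUS) in an MMR gene."""

    variant_id: str
    gene: str
    hgvs_c: str
    variant_type: VariantType
    hgvs_p: str = ""
    gnomad_af: Optional[float] = None
    prior_probability: Optional[float] = None
    spliceai_delta: Optional[float] = None
    functional_evidence: FunctionalEvidence = FunctionalEvidence.none
    clinvar_id: Optional[str] = None
    #: Whether the variant is predicted to truncate the protein through
    #: nonsense-mediated decay (curated; e.g. an exon duplication with known
    #: breakpoints inside the coding sequence).  ``None`` = unknown.
    nmd_predicted: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gene not in MMR_GENES:
            raise ValueError(f"{self.variant_id}: gene {self.gene!r} is not an MMR gene")
        self.variant_type = VariantType(self.variant_type)
        self.functional_evidence = FunctionalEvidence(self.functional_evidence)
        for name in ("gnomad_af", "prior_probability", "spliceai_delta"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.variant_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class IHCPattern:
    """Immunohistochemistry result for the four MMR proteins.

    ``lost_proteins`` is the set of proteins with loss of expression;
    ``patchy_proteins`` marks heterogeneous/patchy loss (a subset of the
    lost set).  An empty lost set means normal staining (pMMR by IHC).
    """

    lost_proteins: frozenset = frozenset()
    patchy_proteins: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lost_proteins", frozenset(self.lost_proteins))
        object.__setattr__(self, "patchy_proteins", frozenset(self.patchy_proteins))
        if not self.lost_proteins <= frozenset(MMR_GENES):
            raise ValueError(f"unknown proteins in IHC pattern: {self.lost_proteins}")
        if not self.patchy_proteins <= self.lost_proteins:
            raise ValueError("patchy_proteins must be a subset of lost_proteins")

    @property
    def is_normal(self) -> bool:
        return not self.lost_proteins

    @classmethod
    def parse(cls, text: str) -> Optional["IHCPattern"]:
        """Parse strings like ``MLH1/PMS2``, ``MLH1+/PMS2`` or ``Normal``.

        A ``+`` suffix marks patchy loss of that protein.  ``NT``/empty
        returns ``None`` (not tested).
        """
        text = text.strip()
        if not text or text.upper() == "NT":
            return None
        if text.lower() == "normal":
            return cls()
        lost, patchy = set(), set()
        for token in text.split("/"):
            token = token.strip()
            is_patchy = token.endswith("+")
            protein = token.rstrip("+ ").strip()
            if protein not in MMR_GENES:
                raise ValueError(f"unparseable IHC token {token!r} in {text!r}")
            lost.add(protein)
            if is_patchy:
                patchy.add(protein)
        return cls(frozenset(lost), frozenset(patchy))

    def format(self) -> str:
        if self.is_normal:
            return "Normal"
        parts = []
        for g in MMR_GENES:
            if g in self.lost_proteins:
                parts.append(g + ("+" if g in self.patchy_proteins else ""))
        return "/".join(parts)


@dataclass
class SomaticCall:
    """A single raw somatic call from a tumor/normal caller pair."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Consequence = Consequence.other
    pass_caller_a: bool = False
    pass_caller_b: bool = False
    tumor_depth: int = 0
    normal_depth: int = 0
    tumor_alt: int = 0
    normal_alt: int = 0
    acmg_class: Optional[int] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        if self.tumor_alt > self.tumor_depth:
            raise ValueError(f"{self.chrom}:{self.pos} tumor_alt > tumor_depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError(f"{self.chrom}:{self.pos} normal_alt > normal_depth")

    @property
    def tumor_vaf(self) -> Optional[float]:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else None

    @property
    def normal_vaf(self) -> Optional[float]:
        return self.normal_alt / self.normal_depth if self.normal_depth else None


@dataclass
class SomaticEvent:
    """A somatic hit assigned to an MMR gene: point mutation or LOH."""

    gene: str
    kind: EventKind
    inactivating: bool = True
    source_call: Optional[SomaticCall] = None

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        if self.gene not in MMR_GENES:
            raise ValueError(f"somatic event gene {self.gene!r} is not an MMR gene")
        if self.kind is EventKind.loh and self.source_call is not None:
            raise ValueError("LOH events carry no source call")

    @classmethod
    def parse_list(cls, text: str) -> list["SomaticEvent"]:
        """Parse a compact event list like ``MLH1:loh;MLH1:mut``."""
        events = []
        for token in filter(None, (t.strip() for t in text.split(";"))):
            gene, _, kind = token.partition(":")
            kind = {"mut": EventKind.single_mutation, "loh": EventKind.loh}[kind]
            events.append(cls(gene=gene, kind=kind, inactivating=True))
        return events

    def format(self) -> str:
        kind = "loh" if self.kind is EventKind.loh else "mut"
        return f"{self.gene}:{kind}"


@dataclass
class MethylationResult:
    """Tumor MLH1 promoter methylation, by one or two independent assays.

    ``methylight_pmr`` is the MethyLight percentage of methylated reference
    (PMR); ``mshrm_percent`` is the methylation-sensitive high-resolution
    melting estimate.  Both in percent units (0-100+).
    """

    methylight_pmr: Optional[float] = None
    mshrm_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.methylight_pmr is None and self.mshrm_percent is None:
            raise ValueError("MethylationResult requires at least one assay value")
        for v in (self.methylight_pmr, self.mshrm_percent):
            if v is not None and v < 0:
                raise ValueError("methylation percentages must be >= 0")


@dataclass
class TumorProfile:
    """A sequenced tumor's molecular dossier."""

    tumor_id: str
    carrier_id: str
    tissue: Tissue
    age_at_diagnosis: float
    ihc: Optional[IHCPattern] = None
    events: list = field(default_factory=list)
    msi_features: Optional[object] = None  # MSIFeatureVector, see mmr_vclass.msi
    braf_v600e: BrafStatus = BrafStatus.not_tested
    mlh1_methylation: Optional[MethylationResult] = None
    #: resolved categorical methylation call for records where only the
    #: positive/negative determination (not the assay values) is known
    mlh1_methylation_positive: Optional[bool] = None
    tmb: Optional[float] = None

    def __post_init__(self) -> None:
        self.tissue = Tissue(self.tissue)
        self.braf_v600e = BrafStatus(self.braf_v600e)
        if self.age_at_diagnosis <= 0:
            raise ValueError(f"{self.tumor_id}: age_at_diagnosis must be positive")


class LesionClass(str, enum.Enum):
    """Coarse class of a recorded lesion.

    Polyps/adenomas and benign polyps are not counted as tumors in
    per-carrier tumor tallies; ``none`` marks unaffected carriers.
    """

    CRC = "CRC"
    EC = "EC"
    other_tumor = "other_tumor"
    polyp = "polyp"
    none = "none"

    @property
    def is_tumor(self) -> bool:
        return self in (LesionClass.CRC, LesionClass.EC, LesionClass.other_tumor)


@dataclass
class Lesion:
    """One lesion row of the carrier table (tumor, polyp or placeholder)."""

    tissue_id: str
    carrier_id: str
    tissue_label: str
    lesion_class: LesionClass
    age_at_diagnosis: Optional[float] = None
    ihc: Optional[IHCPattern] = None
    mlh1_methylation_positive: Optional[bool] = None
    sequenced: bool = False


class ScreenOutcome(str, enum.Enum):
    found = "found"
    not_found = "not_found"
    failed = "failed"
    not_done = "not_done"


class ScreenTissue(str, enum.Enum):
    colonic_mucosa = "colonic_mucosa"
    endometrium = "endometrium"


@dataclass
class CryptScreenRecord:
    """Outcome of screening normal tissue for a dMMR crypt or gland."""

    carrier_id: str
    tissue: ScreenTissue
    outcome: ScreenOutcome
    deficient_protein: Optional[str] = None
    amount_screened: str = ""
    #: "reference" (known pathogenic / non-carrier controls) or "test"
    group: str = "test"
    #: the screened carrier's assessed variant, when in the cohort
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.tissue = ScreenTissue(self.tissue)
        self.outcome = ScreenOutcome(self.outcome)
        if (self.outcome is ScreenOutcome.found) != (self.deficient_protein is not None):
            raise ValueError(
                f"{self.carrier_id}: deficient_protein must be present exactly "
                "when outcome is 'found'"
            )


@dataclass
class Carrier:
    carrier_id: str
    family_id: str
    relationship: str = "Index"
    sex: str = ""
    carried_variants: list = field(default_factory=list)
    is_proband: bool = False
    obligate: bool = False


@dataclass
class Family:
    family_id: str
    #: combined co-segregation likelihood ratio per carried variant
    segregation_lr: dict = field(default_factory=dict)


@dataclass
class EvidenceRecord:
    """Curated per-variant evidence fields feeding the rule engine.

    ``tumor_lr_combined`` may be supplied directly (curated combined tumor
    odds of pathogenicity) or left absent, in which case it is derived from
    the variant's sequenced tumors and a likelihood-ratio table.
    """

    variant_id: str
    tumor_lr_combined: Optional[float] = None
    seg_lr_combined: Optional[float] = None
    n_families: int = 1
    n_tumors_concordant: int = 0
    n_tumors_discordant: int = 0
    case_ihc: Optional[IHCPattern] = None
    printed_class: Optional[int] = None


@dataclass
class Cohort:
    """The full object graph the pipeline operates on."""

    carriers: dict = field(default_factory=dict)
    families: dict = field(default_factory=dict)
    variants: dict = field(default_factory=dict)
    lesions: list = field(default_factory=list)
    tumor_assessments: list = field(default_factory=list)  # list[TumorAssessment]
    evidence: dict = field(default_factory=dict)  # variant_id -> EvidenceRecord
    crypt_screens: list = field(default_factory=list)

    def proband_variants(self) -> list:
        """Variant ids in stable (fixture) order."""
        return list(self.variants)

    def carrier_tumor_counts(self) -> dict:
        counts = {cid: 0 for cid in self.carriers}
        for lesion in self.lesions:
            if lesion.lesion_class.is_tumor:
                counts[lesion.carrier_id] = counts.get(lesion.carrier_id, 0) + 1
        return counts


@dataclass
class TumorAssessment:
    """One (tumor, assessed germline variant) pair.

    A tumor is assessed once per germline variant carried by its host; a
    carrier of two VUS therefore contributes two assessment rows for the
    same tumor.
    """

    tumor: TumorProfile
    variant_id: str
    msi_positive_count: Optional[int] = None
    printed_final: Optional[str] = None


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check referential integrity and value ranges; return violations.

    Raises ``ValueError`` on duplicate identifiers (a hard error because all
    downstream joins assume unique keys); all other problems are reported as
    human-readable violation strings.
    """
    violations: list[str] = []

    seen_lesions = set()
    for lesion in cohort.lesions:
        key = lesion.tissue_id
        if key in seen_lesions:
            raise ValueError(f"duplicate lesion identifier {key!r}")
        seen_lesions.add(key)
        if lesion.carrier_id not in cohort.carriers:
            violations.append(f"lesion {key}: unknown carrier {lesion.carrier_id!r}")
        if lesion.age_at_diagnosis is not None and lesion.age_at_diagnosis <= 0:
            violations.append(f"lesion {key}: non-positive age {lesion.age_at_diagnosis}")

    for carrier in cohort.carriers.values():
        if carrier.family_id not in cohort.families:
            violations.append(
                f"carrier {carrier.carrier_id}: unknown family {carrier.family_id!r}"
            )
        for vid in carrier.carried_variants:
            if vid not in cohort.variants:
                violations.append(
                    f"carrier {carrier.carrier_id}: unknown variant {vid!r}"
                )

    for assessment in cohort.tumor_assessments:
        t = assessment.tumor
        if t.carrier_id not in cohort.carriers:
            violations.append(f"tumor {t.tumor_id}: unknown carrier {t.carrier_id!r}")
        if assessment.variant_id not in cohort.variants:
            violations.append(
                f"tumor {t.tumor_id}: unknown variant {assessment.variant_id!r}"
            )
        if assessment.msi_positive_count is not None and not (
            0 <= assessment.msi_positive_count <= 6
        ):
            violations.append(
                f"tumor {t.tumor_id}: MSI positive count "
                f"{assessment.msi_positive_count} outside 0..6"
            )

    for screen in cohort.crypt_screens:
        # reference-group screens belong to external control carriers
        if screen.group.startswith("reference"):
            continue
        if screen.carrier_id not in cohort.carriers:
            violations.append(
                f"crypt screen: unknown carrier {screen.carrier_id!r}"
            )

    for vid in cohort.evidence:
        if vid not in cohort.variants:
            violations.append(f"evidence record for unknown variant {vid!r}")

    return violations


# ---------------------------------------------------------------------------
# sentinels shared by the TSV readers/writers

ABSENT = ("", "NA", "NT", "na", "nt", "None")


def parse_optional_float(text: str) -> Optional[float]:
    text = text.strip()
    return None if text in ABSENT else float(text)


def parse_optional_int(text: str) -> Optional[int]:
    text = text.strip()
    return None if text in ABSENT else int(text)


def parse_tristate(text: str) -> Optional[bool]:
    """POSITIVE/NEGATIVE/NT style tri-state columns."""
    text = text.strip().upper()
    if text in ("", "NT", "NA"):
        return None
    if text in ("POSITIVE", "YES", "TRUE", "1"):
        return True
    if text in ("NEGATIVE", "NO", "FALSE", "0"):
        return False
    raise ValueError(f"unparseable tri-state value {text!r}")


def format_optional(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)
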