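"""Synthetic cohort generator with ground-truth dMMR mechanism labels.

The generator emulates the world the analysis assumes: carriers of a
germline MMR VUS whose tumors arise by one of five mechanisms --

``lynch_true``
    germline variant plus somatic second hit (single truncating mutation
    or LOH) in the same gene; concordant IHC (subject to a false-negative
    rate); MSI-high feature profile.
``double_somatic_sporadic``
    two somatic inactivating events in a *different* MMR gene with the
    matching IHC pattern; MSI-high.
``mlh1_methylated_phenocopy``
    sporadic MLH1 promoter hypermethylation (PMR >= 10) with MLH1/PMS2
    loss, in a carrier of a VUS in another gene; no somatic events.
``pmmr_sporadic``
    MMR-proficient tumor: normal IHC, no events, microsatellite-stable
    features.
``benign_vus_bystander``
    carrier of two variants; the tumor is fully explained by the
    co-carried variant (concordant IHC + second hit in its gene) while the
    assessed VUS is a bystander.

Every tumor also receives a raw somatic call set (with planted decoys the
consensus filter must remove), germline-heterozygous LOH marker sites,
per-locus microsatellite read-length histograms, an indel catalog drawn
from an ID2/ID7-dominant or background signature mixture, and external
MSI-tool score slots.  All randomness flows from a single seed through
per-(tumor, stream) ``SeedSequence`` children, so any sub-stage is
reproducible in isolation and feature-noise flips are coupled across
noise levels (the flip uniforms do not depend on the noise value).

Depth defaults mirror the sequencing design modeled here: ~906x median
on-target tumor coverage and ~154x for the matched blood normal on a
2.005 Mb capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import MechanismLabel
from .core import (
    MMR_GENES,
    EXPECTED_IHC_LOSS,
    Carrier,
    Cohort,
    Consequence,
    Family,
    GermlineVariant,
    IHCPattern,
    MethylationResult,
    SomaticCall,
    Tissue,
    TumorAssessment,
    TumorProfile,
    VariantType,
)
from .msi import FEATURE_NAMES, IndelCatalog, LocusHistogram

SCENARIOS = (
    "lynch_true",
    "double_somatic_sporadic",
    "mlh1_methylated_phenocopy",
    "pmmr_sporadic",
    "benign_vus_bystander",
)

#: synthetic coordinates of the capture; positions are arbitrary but fixed
PANEL_CHROM = "chr_panel"
PANEL_REGION = ((PANEL_CHROM, 1, 2_005_000),)
GENE_LOCI = {"MLH1": 10_000, "MSH2": 110_000, "MSH6": 210_000, "PMS2": 310_000}
BACKGROUND_START = 500_000
OFF_PANEL_POS = 3_000_000


@dataclass
class ScenarioConfig:
    """Cohort composition and signal strength of the generator."""

    n_lynch_true: int = 50
    n_double_somatic_sporadic: int = 50
    n_mlh1_methylated_phenocopy: int = 50
    n_pmmr_sporadic: int = 50
    n_benign_vus_bystander: int = 50
    second_hit_loh_fraction: float = 0.5
    tumor_mean_depth: int = 906
    normal_mean_depth: int = 154
    panel_megabases: float = 2.005
    ihc_false_negative_rate: float = 0.08
    msi_feature_noise: float = 0.02
    dmmr_tmb_mean: float = 120.0
    pmmr_tmb_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("second_hit_loh_fraction", "ihc_false_negative_rate", "msi_feature_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for s in SCENARIOS:
            if getattr(self, f"n_{s}") < 0:
                raise ValueError("scenario counts must be non-negative")

    def scenario_counts(self) -> dict:
        return {s: getattr(self, f"n_{s}") for s in SCENARIOS}


@dataclass
class TumorTruth:
    mechanism: MechanismLabel
    dmmr: bool
    inactivated_gene: Optional[str]
    second_hit_kind: Optional[str] = None  # "loh" | "mut" for lynch_true


@dataclass
class GroundTruth:
    tumors: dict = field(default_factory=dict)  # tumor_id -> TumorTruth
    variants: dict = field(default_factory=dict)  # variant_id -> pathogenic flag


@dataclass
class TumorRawData:
    """Raw per-tumor inputs, as the pipeline would ingest them."""

    calls: list = field(default_factory=list)
    planted: list = field(default_factory=list)  # the driver events
    decoys: list = field(default_factory=list)  # must not survive filtering
    loh_sites: list = field(default_factory=list)
    histograms: list = field(default_factory=list)
    indel_catalog: Optional[IndelCatalog] = None
    tool_scores: dict = field(default_factory=dict)


def _rng(seed: int, tumor_index: int, stream: int) -> np.random.Generator:
    """Isolated child stream: (seed, tumor, stream) -> Generator."""
    return np.random.default_rng(np.random.SeedSequence([seed, tumor_index, stream]))


# stream ids: keep stable so sub-stages can be regenerated in isolation
_S_SCENARIO, _S_IHC, _S_CALLS, _S_LOH, _S_MSI_FLIP, _S_HIST, _S_CATALOG, _S_TOOLS, _S_BG = range(9)


def generate_cohort(cfg: ScenarioConfig) -> tuple[Cohort, GroundTruth]:
    """Build the carrier/variant/tumor skeleton plus ground truth."""
    cohort = Cohort()
    truth = GroundTruth()
    index = 0
    for scenario in SCENARIOS:
        for _ in range(cfg.scenario_counts()[scenario]):
            _add_case(cohort, truth, cfg, scenario, index)
            index += 1
    return cohort, truth


def _add_case(
    cohort: Cohort, truth: GroundTruth, cfg: ScenarioConfig, scenario: str, index: int
) -> None:
    rng = _rng(cfg.seed, index, _S_SCENARIO)
    cid = f"S{index:04d}"
    fid = f"FS{index:04d}"
    tid = f"T{index:04d}"
    vid = f"SV{index:04d}"

    gene = str(rng.choice(MMR_GENES))
    tissue = Tissue.CRC if rng.random() < 0.5 else Tissue.EC
    age = float(rng.integers(25, 76))

    variant = GermlineVariant(
        variant_id=vid, gene=gene, hgvs_c=f"c.{index + 1}A>G",
        variant_type=VariantType.missense,
    )
    cohort.variants[vid] = variant
    cohort.families[fid] = Family(family_id=fid)
    carrier = Carrier(carrier_id=cid, family_id=fid, is_proband=True,
                      carried_variants=[vid])
    cohort.carriers[cid] = carrier

    ihc: Optional[IHCPattern]
    methylation: Optional[MethylationResult] = None
    second_hit_kind: Optional[str] = None

    if scenario == "lynch_true":
        ihc = IHCPattern(EXPECTED_IHC_LOSS[gene])
        if _rng(cfg.seed, index, _S_IHC).random() < cfg.ihc_false_negative_rate:
            ihc = IHCPattern()  # false-negative IHC: no loss observed
        second_hit_kind = "loh" if rng.random() < cfg.second_hit_loh_fraction else "mut"
        methylation = MethylationResult(methylight_pmr=float(rng.uniform(0, 2)))
        truth.tumors[tid] = TumorTruth(
            MechanismLabel.dmmr_vus_plus_second_hit, True, gene, second_hit_kind
        )
        truth.variants[vid] = True
    elif scenario == "double_somatic_sporadic":
        other = str(rng.choice([g for g in MMR_GENES if g != gene]))
        ihc = IHCPattern(EXPECTED_IHC_LOSS[other])
        methylation = MethylationResult(methylight_pmr=float(rng.uniform(0, 2)))
        truth.tumors[tid] = TumorTruth(MechanismLabel.dmmr_double_somatic, True, other)
        truth.variants[vid] = False
    elif scenario == "mlh1_methylated_phenocopy":
        gene = str(rng.choice(["MSH2", "MSH6", "PMS2"]))
        variant.gene = gene
        ihc = IHCPattern(EXPECTED_IHC_LOSS["MLH1"])
        methylation = MethylationResult(methylight_pmr=float(rng.uniform(15, 70)))
        truth.tumors[tid] = TumorTruth(MechanismLabel.dmmr_mlh1_methylation, True, "MLH1")
        truth.variants[vid] = False
    elif scenario == "pmmr_sporadic":
        ihc = IHCPattern()
        methylation = MethylationResult(methylight_pmr=float(rng.uniform(0, 2)))
        truth.tumors[tid] = TumorTruth(MechanismLabel.pmmr, False, None)
        truth.variants[vid] = False
    else:  # benign_vus_bystander
        other = str(rng.choice([g for g in MMR_GENES if g != gene]))
        vid2 = f"SV{index:04d}b"
        cohort.variants[vid2] = GermlineVariant(
            variant_id=vid2, gene=other, hgvs_c=f"c.{index + 1}del",
            variant_type=VariantType.frameshift,
        )
        carrier.carried_variants.append(vid2)
        ihc = IHCPattern(EXPECTED_IHC_LOSS[other])
        methylation = MethylationResult(methylight_pmr=float(rng.uniform(0, 2)))
        truth.tumors[tid] = TumorTruth(MechanismLabel.vus_benign_bystander, True, other)
        truth.variants[vid] = False
        truth.variants[vid2] = True

    tumor = TumorProfile(
        tumor_id=tid, carrier_id=cid, tissue=tissue, age_at_diagnosis=age,
        ihc=ihc, mlh1_methylation=methylation,
    )
    cohort.tumor_assessments.append(TumorAssessment(tumor=tumor, variant_id=vid))


def _planted_call(rng: np.random.Generator, cfg: ScenarioConfig, gene: str,
                  offset: int) -> SomaticCall:
    tumor_depth = max(60, int(rng.poisson(cfg.tumor_mean_depth)))
    normal_depth = max(55, int(rng.poisson(cfg.normal_mean_depth)))
    vaf = float(rng.uniform(0.25, 0.45))
    return SomaticCall(
        chrom=PANEL_CHROM, pos=GENE_LOCI[gene] + offset, ref="A", alt="T",
        gene=gene, consequence=Consequence.frameshift,
        pass_caller_a=True, pass_caller_b=True,
        tumor_depth=tumor_depth, normal_depth=normal_depth,
        tumor_alt=int(rng.binomial(tumor_depth, vaf)), normal_alt=0,
    )


def generate_somatic_callsets(
    cohort: Cohort, cfg: ScenarioConfig, truth: GroundTruth
) -> dict:
    """Raw per-tumor call sets, LOH markers, MSI histograms and catalogs."""
    signatures = synthetic_signature_matrix()
    raw: dict[str, TumorRawData] = {}
    for index, assessment in enumerate(cohort.tumor_assessments):
        tumor = assessment.tumor
        t = truth.tumors[tumor.tumor_id]
        data = TumorRawData()

        rng = _rng(cfg.seed, index, _S_CALLS)
        # planted driver events
        if t.mechanism is MechanismLabel.dmmr_vus_plus_second_hit and t.second_hit_kind == "mut":
            data.planted.append(_planted_call(rng, cfg, t.inactivated_gene, 100))
        elif t.mechanism is MechanismLabel.dmmr_double_somatic:
            data.planted.append(_planted_call(rng, cfg, t.inactivated_gene, 100))
            data.planted.append(_planted_call(rng, cfg, t.inactivated_gene, 200))
        elif t.mechanism is MechanismLabel.vus_benign_bystander:
            data.planted.append(_planted_call(rng, cfg, t.inactivated_gene, 100))

        # decoys: one-caller-only, low-VAF, off-panel -- all must be filtered
        gene = t.inactivated_gene or "MLH1"
        one_caller = _planted_call(rng, cfg, gene, 300)
        one_caller.pass_caller_b = False
        low_vaf = _planted_call(rng, cfg, gene, 400)
        low_vaf.tumor_alt = int(0.05 * low_vaf.tumor_depth)
        off_panel = _planted_call(rng, cfg, gene, 500)
        off_panel.pos = OFF_PANEL_POS
        data.decoys = [one_caller, low_vaf, off_panel]

        # passenger background (non-MMR genes): drives mutation burden only
        bg_rng = _rng(cfg.seed, index, _S_BG)
        tmb_mean = cfg.dmmr_tmb_mean if t.dmmr else cfg.pmmr_tmb_mean
        n_bg = int(bg_rng.poisson(tmb_mean * cfg.panel_megabases))
        background = []
        for j in range(n_bg):
            depth = max(60, int(bg_rng.poisson(cfg.tumor_mean_depth)))
            ndepth = max(55, int(bg_rng.poisson(cfg.normal_mean_depth)))
            background.append(
                SomaticCall(
                    chrom=PANEL_CHROM, pos=BACKGROUND_START + 10 * j, ref="C", alt="G",
                    gene=f"BG{j % 280}", consequence=Consequence.missense,
                    pass_caller_a=True, pass_caller_b=True,
                    tumor_depth=depth, normal_depth=ndepth,
                    tumor_alt=int(bg_rng.binomial(depth, 0.3)), normal_alt=0,
                )
            )
        data.calls = data.planted + data.decoys + background

        # LOH marker sites: three germline-het markers per MMR gene
        loh_rng = _rng(cfg.seed, index, _S_LOH)
        loh_gene = (
            t.inactivated_gene
            if t.mechanism is MechanismLabel.dmmr_vus_plus_second_hit
            and t.second_hit_kind == "loh"
            else None
        )
        for g in MMR_GENES:
            for m in range(3):
                ndepth = max(55, int(loh_rng.poisson(cfg.normal_mean_depth)))
                tdepth = max(60, int(loh_rng.poisson(cfg.tumor_mean_depth)))
                p_tumor = 0.85 if g == loh_gene else 0.5
                site = SomaticCall(
                    chrom=PANEL_CHROM, pos=GENE_LOCI[g] + 1000 + m, ref="G", alt="A",
                    gene=g, consequence=Consequence.other,
                    tumor_depth=tdepth, normal_depth=ndepth,
                    tumor_alt=int(loh_rng.binomial(tdepth, p_tumor)),
                    normal_alt=int(np.clip(loh_rng.binomial(ndepth, 0.5),
                                           math.ceil(0.32 * ndepth),
                                           math.floor(0.68 * ndepth))),
                )
                data.loh_sites.append(site)

        # per-feature effective dMMR class, with flips coupled across noise
        flip_u = _rng(cfg.seed, index, _S_MSI_FLIP).random(len(FEATURE_NAMES))
        effective = {
            name: t.dmmr ^ bool(flip_u[k] < cfg.msi_feature_noise)
            for k, name in enumerate(FEATURE_NAMES)
        }

        data.histograms = _locus_histograms(
            _rng(cfg.seed, index, _S_HIST), effective["locus_score"]
        )
        data.indel_catalog = _indel_catalog(
            _rng(cfg.seed, index, _S_CATALOG), signatures,
            many=effective["indel_count"], mmr_like=effective["id2_id7_exposure"],
        )
        tool_rng = _rng(cfg.seed, index, _S_TOOLS)
        for slot in ("tool_a", "tool_b", "tool_c"):
            if effective[slot]:
                data.tool_scores[slot] = float(np.clip(tool_rng.normal(0.5, 0.15), 0, 1))
            else:
                data.tool_scores[slot] = float(np.clip(tool_rng.normal(0.05, 0.04), 0, 1))
        raw[tumor.tumor_id] = data
    return raw


def _locus_histograms(rng: np.random.Generator, unstable_class: bool,
                      n_loci: int = 20, reads: int = 100) -> list:
    """Microsatellite read-length histograms for tumor and matched normal."""
    frac = 0.4 if unstable_class else 0.03
    n_unstable = int(rng.binomial(n_loci, frac))
    histograms = []
    for i in range(n_loci):
        mode = int(rng.integers(10, 16))
        normal = {mode - 1: int(0.05 * reads), mode: int(0.9 * reads),
                  mode + 1: int(0.05 * reads)}
        if i < n_unstable:
            tumor_mode = mode - 2
            tumor = {tumor_mode: int(0.6 * reads), mode: int(0.3 * reads),
                     mode - 1: int(0.1 * reads)}
        else:
            tumor = dict(normal)
        histograms.append(LocusHistogram(locus_id=f"MS{i:02d}", tumor=tumor, normal=normal))
    return histograms


def _indel_catalog(rng: np.random.Generator, signatures: pd.DataFrame,
                   many: bool, mmr_like: bool) -> IndelCatalog:
    """Indel catalog drawn from an ID2/ID7-dominant or background mixture."""
    n = int(rng.poisson(60)) if many else int(rng.poisson(3))
    if mmr_like:
        profile = (
            0.55 * signatures["ID2"] + 0.35 * signatures["ID7"]
            + 0.10 * signatures["ID1"]
        )
    else:
        profile = 0.6 * signatures["ID1"] + 0.4 * signatures["ID5"]
    probs = (profile / profile.sum()).to_numpy()
    counts = rng.multinomial(n, probs) if n > 0 else np.zeros(len(probs), dtype=int)
    return IndelCatalog(channel_counts=counts, channel_labels=list(signatures.index))


# ---------------------------------------------------------------------------
# synthetic reference signature matrix


def indel_channel_labels() -> list[str]:
    """The 83-channel small-indel channel set (COSMIC-ID layout)."""
    labels = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        tag = "5+" if length == 5 else str(length)
        labels += [f"{tag}:Del:R:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        tag = "5+" if length == 5 else str(length)
        labels += [f"{tag}:Ins:R:{i}" for i in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        tag = "5+" if length == 5 else str(length)
        labels += [f"{tag}:Del:M:{i}" for i in range(1, max_mh + 1)]
    assert len(labels) == 83
    return labels


def synthetic_signature_matrix(n_signatures: int = 18, seed: int = 20230113) -> pd.DataFrame:
    """SYNTHETIC stand-in for a reference small-indel signature matrix.

    Channels x signatures (ID1..ID18), columns normalized to sum to one.
    This is *not* the COSMIC reference: it is a deterministic synthetic
    matrix whose ID2 and ID7 columns concentrate on single-base deletions
    at long homopolymer runs (the channels enriched in MMR-deficient
    tumors), so that refitting behaves qualitatively like the real
    signatures.  Use a real reference matrix for real data.
    """
    labels = indel_channel_labels()
    rng = np.random.default_rng(seed)
    n_channels = len(labels)
    matrix = rng.dirichlet(np.full(n_channels, 0.08), size=n_signatures).T

    def concentrate(col: int, channels: dict) -> None:
        profile = np.full(n_channels, 0.001)
        for label, weight in channels.items():
            profile[labels.index(label)] = weight
        matrix[:, col] = profile / profile.sum()

    # ID2-like: 1bp T deletions at long T homopolymers
    concentrate(1, {"1:Del:T:5": 0.6, "1:Del:T:4": 0.25, "1:Del:T:3": 0.08})
    # ID7-like: 1bp deletions at moderate runs, both bases
    concentrate(6, {"1:Del:T:2": 0.35, "1:Del:C:2": 0.25, "1:Del:T:3": 0.2,
                    "1:Del:C:3": 0.12})
    # ID1-like: 1bp T insertions at long runs (clock-like background)
    concentrate(0, {"1:Ins:T:5": 0.5, "1:Ins:T:4": 0.3, "1:Ins:T:3": 0.12})
    matrix /= matrix.sum(axis=0, keepdims=True)
    return pd.DataFrame(
        matrix, index=labels, columns=[f"ID{i + 1}" for i in range(n_signatures)]
    )
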