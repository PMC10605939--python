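"""End-to-end drivers: fixture analysis, synthetic recovery, reports.

Two entry points matter:

* :func:`run_fixture_analysis` runs the classifier stack over a curated
  cohort (the shipped fixture bundle or user TSVs) and emits the cohort
  summary.

* :func:`run_synthetic_pipeline` generates a synthetic cohort with ground
  truth, pushes its raw per-tumor data through the *full* computational
  path (consensus filtering, LOH testing, event classification, signature
  refitting, locus scoring, additive MSI combination, mechanism decision
  tree) and scores mechanism recovery against the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .classify import (
    AssessmentResult,
    CohortResults,
    CohortSummary,
    MechanismLabel,
    RuleSet,
    TumorLRTable,
    analyze_cohort,
    cohort_summary,
)
from .core import Cohort
from .fixtures import load_fixture_bundle
from .msi import (
    MSIThresholds,
    msi_feature_vector,
    msi_locus_instability_score,
    refit_indel_signatures,
)
from .somatic import (
    FilterConfig,
    LOHConfig,
    call_loh,
    classify_somatic_events,
    consensus_filter,
    tumor_mutation_burden,
)
from .synthetic import (
    PANEL_REGION,
    GroundTruth,
    ScenarioConfig,
    generate_cohort,
    generate_somatic_callsets,
    synthetic_signature_matrix,
)


def run_fixture_analysis(
    cohort: Optional[Cohort] = None,
    rules: Optional[RuleSet] = None,
) -> tuple[CohortResults, CohortSummary]:
    """Analyze a curated cohort (defaults to the shipped fixture bundle)."""
    cohort = cohort if cohort is not None else load_fixture_bundle("all")
    results = analyze_cohort(cohort, rules=rules, lr_table=TumorLRTable.default())
    return results, cohort_summary(cohort, results)


@dataclass
class SyntheticRunResult:
    cohort: Cohort
    truth: GroundTruth
    results: CohortResults
    summary: CohortSummary
    #: tumor_id -> (truth mechanism, predicted mechanism or None)
    per_tumor: dict = field(default_factory=dict)

    @property
    def recovery(self) -> float:
        if not self.per_tumor:
            return float("nan")
        hits = sum(1 for t, p in self.per_tumor.values() if t == p)
        return hits / len(self.per_tumor)

    def recovery_by_mechanism(self) -> dict:
        out: dict = {}
        for truth_label, predicted in self.per_tumor.values():
            n_ok, n = out.get(truth_label, (0, 0))
            out[truth_label] = (n_ok + (truth_label == predicted), n + 1)
        return {k: ok / n for k, (ok, n) in out.items()}


def run_synthetic_pipeline(
    cfg: Optional[ScenarioConfig] = None,
    rules: Optional[RuleSet] = None,
    thresholds: Optional[MSIThresholds] = None,
) -> SyntheticRunResult:
    """Generate, process and score a synthetic cohort end to end."""
    cfg = cfg or ScenarioConfig()
    thresholds = thresholds or MSIThresholds()
    filter_cfg = FilterConfig(
        panel_region=PANEL_REGION, target_megabases=cfg.panel_megabases
    )
    loh_cfg = LOHConfig()
    signatures = synthetic_signature_matrix()

    cohort, truth = generate_cohort(cfg)
    raw = generate_somatic_callsets(cohort, cfg, truth)

    for assessment in cohort.tumor_assessments:
        tumor = assessment.tumor
        data = raw[tumor.tumor_id]
        filtered = consensus_filter(data.calls, filter_cfg)
        loh = call_loh(data.loh_sites, loh_cfg)
        tumor.events = classify_somatic_events(filtered, loh)
        tumor.tmb = tumor_mutation_burden(filtered, filter_cfg)

        values = dict(data.tool_scores)
        values["locus_score"] = msi_locus_instability_score(data.histograms)
        values["indel_count"] = data.indel_catalog.total
        refit = refit_indel_signatures(data.indel_catalog, signatures)
        values["id2_id7_exposure"] = (
            refit.id2_id7_exposure if data.indel_catalog.total > 0 else None
        )
        tumor.msi_features = msi_feature_vector(values, thresholds)

    results = analyze_cohort(cohort, rules=rules, lr_table=TumorLRTable.default())
    per_tumor = {}
    for res in results.assessments:
        tid = res.assessment.tumor.tumor_id
        per_tumor[tid] = (truth.tumors[tid].mechanism, res.final.label)
    return SyntheticRunResult(
        cohort=cohort,
        truth=truth,
        results=results,
        summary=cohort_summary(cohort, results),
        per_tumor=per_tumor,
    )


def write_report(summary: CohortSummary, results: CohortResults, outdir: str | Path) -> dict:
    """Write the JSON summary plus per-variant / per-tumor TSV reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"summary": outdir / "summary.json"}
    paths["summary"].write_text(
        json.dumps(summary.as_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    lines = ["variant_id\tgene\tclass\tlabel\tposterior"]
    for vid, klass in results.variant_classes.items():
        profile = results.profiles[vid]
        post = "NA" if profile.posterior_probability is None else (
            f"{profile.posterior_probability:.6f}"
        )
        lines.append(f"{vid}\t{profile.gene}\t{klass.klass}\t{klass.label.value}\t{post}")
    paths["variants"] = outdir / "variant_classes.tsv"
    paths["variants"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["tumor_id\tvariant_id\tmsi_high\tsecond_hit\tfinal_label\timplicated_gene"]
    for res in results.assessments:
        label = res.final.label.value if res.final.label else "UNRESOLVED"
        lines.append(
            "\t".join(
                [
                    res.assessment.tumor.tumor_id,
                    res.assessment.variant_id,
                    str(res.msi_high).lower(),
                    str(res.second_hit.present).lower(),
                    label,
                    res.final.implicated_gene or "NA",
                ]
            )
        )
    paths["tumors"] = outdir / "tumor_labels.tsv"
    paths["tumors"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def format_summary(summary: CohortSummary) -> str:
    """Human-readable cohort summary; every number is a summary field."""
    s = summary

    def pct(num: int, den: int) -> str:
        return "NA" if den == 0 else f"{100.0 * num / den:.1f}%"

    lines = [
        f"variants: {s.n_variants} "
        f"(class4 {s.class_counts[4]} [{pct(s.class_counts[4], s.n_variants)}], "
        f"class1-2 {s.class_counts[1] + s.class_counts[2]}, "
        f"class3 {s.class_counts[3]})",
        f"carriers: {s.n_carriers} in {s.n_families} families; "
        f"multiple tumors {s.n_multi_tumor_carriers} "
        f"[{pct(s.n_multi_tumor_carriers, s.n_carriers)}]",
        f"proband IHC concordance: {s.proband_concordant} concordant "
        f"[{pct(s.proband_concordant, s.n_variants)}], "
        f"{s.proband_discordant} discordant, {s.proband_no_loss} no loss",
        f"tumors sequenced: {s.n_tumors_sequenced}; "
        f"MSI-H/dMMR {s.n_msi_high}, of which with IHC loss "
        f"{s.n_msi_high_with_ihc_loss} [{pct(s.n_msi_high_with_ihc_loss, s.n_msi_high)}]",
        f"IHC-concordant tumors: {s.n_ihc_concordant_tumors}; with second hit "
        f"{s.n_concordant_with_second_hit} "
        f"[{pct(s.n_concordant_with_second_hit, s.n_ihc_concordant_tumors)}]",
        f"LP-variant tumors: {s.n_lp_tumors}; MSI-H {s.n_lp_msi_high} "
        f"[{pct(s.n_lp_msi_high, s.n_lp_tumors)}], second hit {s.n_lp_second_hit} "
        f"[{pct(s.n_lp_second_hit, s.n_lp_tumors)}]",
        f"double-somatic carriers: {s.n_double_somatic_carriers}",
        f"crypt/gland screening (test group): {s.n_test_screens} screened, "
        f"{s.n_screens_evaluable} evaluable, {s.n_screens_found} found "
        f"[{pct(s.n_screens_found, s.n_screens_evaluable)}]; "
        f"LP evaluable {s.n_lp_screens_evaluable}, found {s.n_lp_screens_found} "
        f"[{pct(s.n_lp_screens_found, s.n_lp_screens_evaluable)}]",
    ]
    return "\n".join(lines)
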