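"""Frozen cohort fixture bundle and TSV readers/writers.

The shipped fixtures are a row-level transcription of a published
25-variant MMR VUS study cohort: the carrier/family table, the per-variant
evidence table, the sequenced-tumor molecular table and the normal-tissue
crypt/gland screening table.  They are frozen: a checksum mismatch on load
is a hard error.

All interchange formats are plain UTF-8 TSV with ``NA``/``NT`` sentinels
for absent / not-tested values, so fixtures stay human-diffable.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .core import (
    Carrier,
    Cohort,
    CryptScreenRecord,
    EvidenceRecord,
    Family,
    GermlineVariant,
    IHCPattern,
    Lesion,
    LesionClass,
    ScreenOutcome,
    ScreenTissue,
    SomaticEvent,
    Tissue,
    TumorAssessment,
    TumorProfile,
    format_optional,
    parse_optional_float,
    parse_optional_int,
    parse_tristate,
    validate_cohort,
)

FIXTURE_FILES = (
    "families.tsv",
    "carriers.tsv",
    "variants.tsv",
    "table1_lesions.tsv",
    "table2_evidence.tsv",
    "table3_tumors.tsv",
    "table4_crypt_screens.tsv",
)

BUNDLES = ("table1", "table2", "table3", "table4", "all")


class FixtureIntegrityError(RuntimeError):
    pass


def _fixture_dir():
    return resources.files("mmr_vclass") / "fixtures"


def _read_fixture_text(name: str) -> str:
    text = (_fixture_dir() / name).read_text(encoding="utf-8")
    _verify_checksum(name, text)
    return text


_checksums_cache: Optional[dict] = None


def _verify_checksum(name: str, text: str) -> None:
    global _checksums_cache
    if _checksums_cache is None:
        path = _fixture_dir() / "CHECKSUMS.json"
        _checksums_cache = json.loads(path.read_text(encoding="utf-8"))
    expected = _checksums_cache.get(name)
    actual = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if expected is None or actual != expected:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch (fixtures are frozen): "
            f"{actual} != {expected}"
        )


def _rows(text: str) -> list[dict]:
    return list(csv.DictReader(io.StringIO(text), delimiter="\t"))


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _parse_optional_bool(text: str) -> Optional[bool]:
    text = text.strip()
    if text in ("", "NA", "NT"):
        return None
    return _parse_bool(text)


# ---------------------------------------------------------------------------
# readers (operate on raw TSV text so user files load the same way)


def read_families(text: str) -> dict:
    return {r["family_id"]: Family(family_id=r["family_id"]) for r in _rows(text)}


def read_carriers(text: str) -> dict:
    carriers = {}
    for r in _rows(text):
        carried = [v for v in r["carried_variants"].split(",") if v and v != "NA"]
        carriers[r["carrier_id"]] = Carrier(
            carrier_id=r["carrier_id"],
            family_id=r["family_id"],
            relationship=r["relationship"],
            sex=r["sex"],
            carried_variants=carried,
            is_proband=_parse_bool(r["is_proband"]),
            obligate=_parse_bool(r["obligate"]),
        )
    return carriers


def read_variants(text: str) -> dict:
    variants = {}
    for r in _rows(text):
        variants[r["variant_id"]] = GermlineVariant(
            variant_id=r["variant_id"],
            gene=r["gene"],
            hgvs_c=r["hgvs_c"],
            hgvs_p=r["hgvs_p"],
            variant_type=r["variant_type"],
            clinvar_id=None if r["clinvar_id"] == "NA" else r["clinvar_id"],
            gnomad_af=parse_optional_float(r["gnomad_af"]),
            prior_probability=parse_optional_float(r["prior_probability"]),
            spliceai_delta=parse_optional_float(r["spliceai_delta"]),
            functional_evidence=r["functional_evidence"],
            nmd_predicted=_parse_optional_bool(r["nmd_predicted"]),
        )
    return variants


def read_lesions(text: str) -> list:
    lesions = []
    for r in _rows(text):
        lesions.append(
            Lesion(
                tissue_id=r["tissue_id"],
                carrier_id=r["carrier_id"],
                tissue_label=r["tissue_label"],
                lesion_class=LesionClass(r["lesion_class"]),
                age_at_diagnosis=parse_optional_float(r["age"]),
                ihc=IHCPattern.parse(r["ihc"]),
                mlh1_methylation_positive=parse_tristate(r["mlh1_methylation"]),
                sequenced=_parse_bool(r["sequenced"]),
            )
        )
    return lesions


def read_evidence(text: str) -> dict:
    evidence = {}
    for r in _rows(text):
        evidence[r["variant_id"]] = EvidenceRecord(
            variant_id=r["variant_id"],
            tumor_lr_combined=parse_optional_float(r["tumor_lr"]),
            seg_lr_combined=parse_optional_float(r["seg_lr"]),
            n_families=int(r["n_families"]),
            n_tumors_concordant=int(r["n_tumors_concordant"]),
            n_tumors_discordant=int(r["n_tumors_discordant"]),
            case_ihc=IHCPattern.parse(r["case_ihc"]),
            printed_class=parse_optional_int(r["printed_class"]),
        )
    return evidence


def read_tumor_assessments(text: str) -> list:
    assessments = []
    for r in _rows(text):
        events = SomaticEvent.parse_list(r["second_hit_events"]) + SomaticEvent.parse_list(
            r["other_events"]
        )
        tumor = TumorProfile(
            tumor_id=r["tissue_id"],
            carrier_id=r["carrier_id"],
            tissue=Tissue(r["tissue"]),
            age_at_diagnosis=float(r["age"]),
            ihc=IHCPattern.parse(r["ihc"]),
            mlh1_methylation_positive=parse_tristate(r["mlh1_methylation"]),
            tmb=parse_optional_float(r["tmb"]),
            events=events,
        )
        assessments.append(
            TumorAssessment(
                tumor=tumor,
                variant_id=r["variant_id"],
                msi_positive_count=parse_optional_int(r["msi_positive_count"]),
                printed_final=r["printed_final"] or None,
            )
        )
    return assessments


def read_crypt_screens(text: str) -> list:
    screens = []
    for r in _rows(text):
        outcome = ScreenOutcome(r["outcome"])
        screens.append(
            CryptScreenRecord(
                carrier_id=r["carrier_id"],
                tissue=ScreenTissue(r["screen_tissue"]),
                outcome=outcome,
                deficient_protein=(
                    None if r["deficient_protein"] == "NA" else r["deficient_protein"]
                ),
                amount_screened=r["amount_screened"],
                group=r["group"],
                variant_id=None if r["variant_id"] == "NA" else r["variant_id"],
            )
        )
    return screens


def load_fixture_bundle(name: str = "all") -> Cohort:
    """Load a frozen fixture bundle as a validated cohort.

    ``table1`` loads the carrier/family/variant/lesion graph; ``table2``
    adds the evidence table, ``table3`` the sequenced tumors, ``table4``
    the crypt/gland screens; ``all`` loads everything.  The result always
    passes :func:`validate_cohort` with zero violations.
    """
    if name not in BUNDLES:
        raise ValueError(f"unknown bundle {name!r}; expected one of {BUNDLES}")
    cohort = Cohort(
        families=read_families(_read_fixture_text("families.tsv")),
        carriers=read_carriers(_read_fixture_text("carriers.tsv")),
        variants=read_variants(_read_fixture_text("variants.tsv")),
        lesions=read_lesions(_read_fixture_text("table1_lesions.tsv")),
    )
    if name in ("table2", "table3", "all"):
        cohort.evidence = read_evidence(_read_fixture_text("table2_evidence.tsv"))
    if name in ("table3", "all"):
        cohort.tumor_assessments = read_tumor_assessments(
            _read_fixture_text("table3_tumors.tsv")
        )
    if name in ("table4", "all"):
        cohort.crypt_screens = read_crypt_screens(
            _read_fixture_text("table4_crypt_screens.tsv")
        )
    violations = validate_cohort(cohort)
    if violations:
        raise FixtureIntegrityError(f"fixture bundle invalid: {violations}")
    return cohort


# ---------------------------------------------------------------------------
# writers (round-trip support for user cohorts)


def _write_tsv(path: Path, header: list[str], rows: Iterable[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write a cohort back to the TSV dialect the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["families"] = outdir / "families.tsv"
    _write_tsv(paths["families"], ["family_id"], [[f] for f in cohort.families])

    paths["carriers"] = outdir / "carriers.tsv"
    _write_tsv(
        paths["carriers"],
        ["carrier_id", "family_id", "relationship", "sex", "carried_variants",
         "is_proband", "obligate"],
        [
            [c.carrier_id, c.family_id, c.relationship, c.sex,
             ",".join(c.carried_variants), format_optional(c.is_proband),
             format_optional(c.obligate)]
            for c in cohort.carriers.values()
        ],
    )

    paths["variants"] = outdir / "variants.tsv"
    _write_tsv(
        paths["variants"],
        ["variant_id", "family_id", "gene", "hgvs_c", "hgvs_p", "variant_type",
         "clinvar_id", "gnomad_af", "prior_probability", "spliceai_delta",
         "functional_evidence", "nmd_predicted"],
        [
            [v.variant_id, "NA", v.gene, v.hgvs_c, v.hgvs_p, v.variant_type.value,
             format_optional(v.clinvar_id), format_optional(v.gnomad_af),
             format_optional(v.prior_probability), format_optional(v.spliceai_delta),
             v.functional_evidence.value, format_optional(v.nmd_predicted)]
            for v in cohort.variants.values()
        ],
    )

    paths["lesions"] = outdir / "table1_lesions.tsv"
    _write_tsv(
        paths["lesions"],
        ["tissue_id", "carrier_id", "tissue_label", "lesion_class", "age", "ihc",
         "mlh1_methylation", "sequenced"],
        [
            [l.tissue_id, l.carrier_id, l.tissue_label, l.lesion_class.value,
             format_optional(l.age_at_diagnosis),
             l.ihc.format() if l.ihc is not None else "NT",
             {True: "POSITIVE", False: "NEGATIVE", None: "NT"}[
                 l.mlh1_methylation_positive],
             format_optional(l.sequenced)]
            for l in cohort.lesions
        ],
    )

    paths["tumors"] = outdir / "table3_tumors.tsv"
    _write_tsv(
        paths["tumors"],
        ["row", "carrier_id", "tissue_id", "variant_id", "tissue", "age", "ihc",
         "mlh1_methylation", "tmb", "msi_positive_count", "second_hit_events",
         "other_events", "printed_final"],
        [
            [i + 1, a.tumor.carrier_id, a.tumor.tumor_id, a.variant_id,
             a.tumor.tissue.value, a.tumor.age_at_diagnosis,
             a.tumor.ihc.format() if a.tumor.ihc is not None else "NT",
             {True: "POSITIVE", False: "NEGATIVE", None: "NT"}[
                 a.tumor.mlh1_methylation_positive],
             format_optional(a.tumor.tmb),
             format_optional(a.msi_positive_count),
             ";".join(e.format() for e in a.tumor.events), "",
             a.printed_final or ""]
            for i, a in enumerate(cohort.tumor_assessments)
        ],
    )
    return paths
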