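"""MSI/dMMR calling from tumor sequencing features.

Tumor microsatellite instability (MSI) / mismatch-repair deficiency (dMMR)
status is determined by an additive combination of six features:

1-4. four external MSI tool scores (slots accepting precomputed values;
     one slot can be filled by the bespoke per-locus instability scorer
     shipped here),
5.   the somatic small insertion/deletion (indel) count, and
6.   the combined exposure of the MMR-deficiency indel signatures ID2 and
     ID7 obtained by non-negative least-squares refitting of the tumor's
     indel catalog onto a reference signature matrix.

Each feature is thresholded to a boolean flag; a tumor with three or more
positive features is called MSI-H/dMMR.  An absent feature counts as
negative -- the rule is defined over a fixed panel of six features, so the
denominator never shrinks.

The numeric cutoffs shipped as defaults are calibrated on the synthetic
cohort generator, not taken from any external benchmark, and are all
configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

TOOL_SLOTS = ("tool_a", "tool_b", "tool_c", "locus_score")
FEATURE_NAMES = TOOL_SLOTS + ("indel_count", "id2_id7_exposure")


@dataclass
class MSIThresholds:
    """Per-feature positivity cutoffs (feature >= cutoff is positive)."""

    tool_a: float = 0.2
    tool_b: float = 0.2
    tool_c: float = 0.2
    locus_score: float = 0.2
    indel_count: float = 10.0
    id2_id7_exposure: float = 0.2

    def cutoff(self, feature: str) -> float:
        return getattr(self, feature)


@dataclass
class MSIFeatureVector:
    """Thresholded MSI features for one tumor."""

    flags: dict = field(default_factory=dict)  # feature name -> bool
    values: dict = field(default_factory=dict)  # feature name -> float or None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            self.flags.setdefault(name, False)

    @property
    def positive_count(self) -> int:
        return sum(bool(self.flags[name]) for name in FEATURE_NAMES)

    @classmethod
    def from_positive_count(cls, count: int) -> "MSIFeatureVector":
        """Build a vector carrying only a known positive count.

        Used for curated records that report the additive tally (the
        ``x/6`` notation) without the underlying feature values.
        """
        if not 0 <= count <= 6:
            raise ValueError(f"positive count {count} outside 0..6")
        flags = {name: i < count for i, name in enumerate(FEATURE_NAMES)}
        return cls(flags=flags)


@dataclass
class IndelCatalog:
    """Counts of somatic small indels over a fixed channel set."""

    channel_counts: np.ndarray
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.channel_counts = np.asarray(self.channel_counts, dtype=float)
        if self.channel_counts.ndim != 1:
            raise ValueError("channel_counts must be a vector")
        if len(self.channel_counts) != len(self.channel_labels):
            raise ValueError("channel_counts and channel_labels length mismatch")
        if np.any(self.channel_counts < 0):
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.channel_counts.sum())


@dataclass
class SignatureRefit:
    exposures: dict  # signature name -> fraction (sums to 1 when fit)
    id2_id7_exposure: float
    residual: float


def refit_indel_signatures(
    catalog: IndelCatalog,
    signatures,  # pandas DataFrame, channels x signatures
    id_signatures: Sequence[str] = ("ID2", "ID7"),
) -> SignatureRefit:
    """Refit an indel catalog onto a signature matrix by NNLS.

    The catalog is normalized to channel frequencies before fitting so the
    result is invariant to total mutation load; exposures are renormalized
    to sum to one.  ``id2_id7_exposure`` is the summed exposure of the
    MMR-deficiency signatures (ID2 + ID7 by default).

    A zero catalog yields all-zero exposures with a warning.
    """
    matrix = np.asarray(signatures, dtype=float)
    names = list(signatures.columns)
    missing = [s for s in id_signatures if s not in names]
    if missing:
        raise ValueError(f"signature matrix lacks columns {missing}")
    if np.any(matrix < 0):
        raise ValueError("signature matrix entries must be non-negative")
    if catalog.total == 0:
        warnings.warn("zero indel catalog: exposures undefined, returning zeros")
        return SignatureRefit(
            exposures={name: 0.0 for name in names}, id2_id7_exposure=0.0, residual=0.0
        )
    target = catalog.channel_counts / catalog.total
    coef, residual = nnls(matrix, target)
    total = coef.sum()
    if total > 0:
        coef = coef / total
    exposures = dict(zip(names, coef.tolist()))
    return SignatureRefit(
        exposures=exposures,
        id2_id7_exposure=float(sum(exposures[s] for s in id_signatures)),
        residual=float(residual),
    )


@dataclass
class LocusHistogram:
    """Read counts per microsatellite repeat length for tumor and normal."""

    locus_id: str
    tumor: Mapping[int, int]
    normal: Mapping[int, int]


def _modal_length(hist: Mapping[int, int]) -> int:
    # ties break toward the shorter repeat, deterministically
    return min(sorted(hist), key=lambda k: (-hist[k], k))


def msi_locus_instability_score(
    loci: Sequence[LocusHistogram],
    min_reads: int = 20,
    outside_mode_fraction: float = 0.2,
) -> Optional[float]:
    """Fraction of assessable microsatellite loci that are unstable.

    A locus is assessable when both samples have >= ``min_reads`` reads.
    It is unstable when the tumor's modal repeat length differs from the
    normal's, or when the fraction of tumor reads outside the normal's
    modal length exceeds ``outside_mode_fraction``.  Returns ``None`` when
    no locus is assessable.
    """
    assessable = unstable = 0
    for locus in loci:
        t_total, n_total = sum(locus.tumor.values()), sum(locus.normal.values())
        if t_total < min_reads or n_total < min_reads:
            continue
        assessable += 1
        normal_mode = _modal_length(locus.normal)
        tumor_mode = _modal_length(locus.tumor)
        outside = 1.0 - locus.tumor.get(normal_mode, 0) / t_total
        if tumor_mode != normal_mode or outside > outside_mode_fraction:
            unstable += 1
    if assessable == 0:
        return None
    return unstable / assessable


def msi_feature_vector(
    values: Mapping[str, Optional[float]],
    thresholds: MSIThresholds | None = None,
) -> MSIFeatureVector:
    """Threshold raw feature values into a six-flag vector.

    ``values`` maps feature names (see :data:`FEATURE_NAMES`) to raw
    values; missing or ``None`` entries yield a negative flag.
    """
    thresholds = thresholds or MSIThresholds()
    unknown = set(values) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown MSI features: {sorted(unknown)}")
    flags, raw = {}, {}
    for name in FEATURE_NAMES:
        v = values.get(name)
        raw[name] = v
        flags[name] = v is not None and v >= thresholds.cutoff(name)
    return MSIFeatureVector(flags=flags, values=raw)


def additive_combination(fv: MSIFeatureVector | int) -> tuple[str, int]:
    """Call MSI-H/dMMR when three or more of the six features are positive.

    Accepts either a feature vector or a bare positive count.  Returns
    ``(status, positive_count)`` with status ``"MSI-H/dMMR"`` or
    ``"MSS/pMMR"``.
    """
    count = fv if isinstance(fv, int) else fv.positive_count
    if not 0 <= count <= 6:
        raise ValueError(f"positive count {count} outside 0..6")
    return ("MSI-H/dMMR" if count >= 3 else "MSS/pMMR", count)


def is_msi_high(fv: MSIFeatureVector | int) -> bool:
    return additive_combination(fv)[0] == "MSI-H/dMMR"
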