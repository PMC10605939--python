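"""Somatic call filtering, LOH calling, second hits and mutation burden.

Raw tumor/normal caller output (one record per candidate variant, with PASS
flags from two independent callers and depths/alt counts for both samples)
is reduced to a set of gene-level inactivating events: single somatic
mutations and loss of heterozygosity (LOH).  These events drive the
second-hit and double-somatic determinations used in variant
interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import fisher_exact

from .core import (
    MMR_GENES,
    TRUNCATING_CONSEQUENCES,
    EventKind,
    GermlineVariant,
    SomaticCall,
    SomaticEvent,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Consensus filter thresholds for somatic calls.

    Defaults: PASS by both callers, depth >= 50 in tumor and matched
    normal, tumor variant allele fraction >= 10%, restricted to the capture
    region.  ``target_megabases`` is the capture footprint used for the
    tumor mutation burden denominator (2.005 Mb for the hereditary
    CRC/EC panel modeled here).
    """

    min_depth: int = 50
    min_vaf: float = 0.10
    require_both_callers: bool = True
    #: set of (chrom, start, end) 1-based inclusive intervals; empty = no
    #: positional restriction.
    panel_region: tuple = ()
    target_megabases: float = 2.005

    def __post_init__(self) -> None:
        if not (0.0 < self.min_vaf < 1.0):
            raise ValueError("min_vaf must lie strictly in (0, 1)")
        if self.target_megabases <= 0:
            raise ValueError("target_megabases must be positive")

    def in_panel(self, chrom: str, pos: int) -> bool:
        if not self.panel_region:
            return True
        return any(c == chrom and s <= pos <= e for c, s, e in self.panel_region)


@dataclass
class LOHConfig:
    """Parameters of the VAF-shift LOH test.

    A gene is called LOH when at least ``min_informative_markers`` germline
    heterozygous sites show both an effect-size shift
    (|tumor VAF - normal VAF| >= ``delta_vaf_min``) and a significant
    two-sided Fisher exact test of tumor vs normal alt fraction at level
    ``alpha``, Bonferroni-corrected over the gene's markers.
    """

    delta_vaf_min: float = 0.15
    alpha: float = 0.01
    min_informative_markers: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly in (0, 1)")


def passes_consensus_filter(call: SomaticCall, cfg: FilterConfig) -> bool:
    """Predicate form of the consensus filter (used as its own oracle)."""
    if cfg.require_both_callers and not (call.pass_caller_a and call.pass_caller_b):
        return False
    if not cfg.require_both_callers and not (call.pass_caller_a or call.pass_caller_b):
        return False
    if call.tumor_depth < cfg.min_depth or call.normal_depth < cfg.min_depth:
        return False
    if call.tumor_depth == 0:
        return False
    if call.tumor_alt / call.tumor_depth < cfg.min_vaf:
        return False
    return cfg.in_panel(call.chrom, call.pos)


def consensus_filter(calls: Sequence[SomaticCall], cfg: FilterConfig) -> list[SomaticCall]:
    """Retain calls PASSed by both callers with adequate depth and VAF.

    Order-preserving.  A call with zero tumor depth that otherwise claims
    alt support is dropped with a warning rather than raising: such records
    occur in malformed caller exports.
    """
    kept = []
    for call in calls:
        if call.tumor_depth == 0 and (call.pass_caller_a or call.pass_caller_b):
            logger.warning(
                "dropping zero-depth call %s:%s %s>%s",
                call.chrom, call.pos, call.ref, call.alt,
            )
            continue
        if passes_consensus_filter(call, cfg):
            kept.append(call)
    return kept


@dataclass
class LOHResult:
    gene: str
    #: True = LOH called; False = testable but not called; None = no
    #: informative markers (untestable, never reported as "no LOH").
    loh_flag: Optional[bool]
    min_p: Optional[float] = None
    n_informative: int = 0


def call_loh(
    sites: Sequence[SomaticCall],
    cfg: LOHConfig | None = None,
    genes: Sequence[str] = MMR_GENES,
) -> list[LOHResult]:
    """Call per-gene LOH from germline heterozygous marker sites.

    ``sites`` are genotyped positions with tumor and normal depths/alt
    counts; only sites heterozygous in the normal (normal VAF in
    [0.3, 0.7]) are informative.  See :class:`LOHConfig` for the test.
    """
    cfg = cfg or LOHConfig()
    results = []
    for gene in genes:
        markers = [
            s
            for s in sites
            if s.gene == gene
            and s.normal_depth > 0
            and s.tumor_depth > 0
            and 0.3 <= s.normal_alt / s.normal_depth <= 0.7
        ]
        if not markers:
            results.append(LOHResult(gene=gene, loh_flag=None))
            continue
        n_hits = 0
        min_p: Optional[float] = None
        for s in markers:
            delta = abs(s.tumor_alt / s.tumor_depth - s.normal_alt / s.normal_depth)
            table = [
                [s.tumor_alt, s.tumor_depth - s.tumor_alt],
                [s.normal_alt, s.normal_depth - s.normal_alt],
            ]
            p = float(fisher_exact(table, alternative="two-sided")[1])
            p_adj = min(1.0, p * len(markers))
            min_p = p_adj if min_p is None else min(min_p, p_adj)
            if delta >= cfg.delta_vaf_min and p_adj < cfg.alpha:
                n_hits += 1
        results.append(
            LOHResult(
                gene=gene,
                loh_flag=n_hits >= cfg.min_informative_markers,
                min_p=min_p,
                n_informative=len(markers),
            )
        )
    return results


def is_inactivating(call: SomaticCall) -> bool:
    """Inactivating tier for a somatic call.

    A curated ACMG class of 4 or 5 wins when present; otherwise truncating
    consequences (nonsense, frameshift, splice) count as inactivating and
    missense/synonymous do not.
    """
    if call.acmg_class is not None:
        return call.acmg_class >= 4
    return call.consequence in TRUNCATING_CONSEQUENCES


def classify_somatic_events(
    filtered_calls: Sequence[SomaticCall],
    loh_results: Sequence[LOHResult] = (),
    mmr_genes: Sequence[str] = MMR_GENES,
) -> list[SomaticEvent]:
    """Turn filtered calls plus LOH flags into gene-level somatic events.

    Every filtered call in an MMR gene becomes a ``single_mutation`` event
    (tiered inactivating or not); every gene with a positive LOH flag adds
    one ``loh`` event.  Calls outside the MMR genes contribute no events
    (they still count toward mutation burden).  Multiple events per gene
    are all retained -- the analysis counts events, it does not dedupe.
    """
    events = []
    for call in filtered_calls:
        if call.gene in mmr_genes:
            events.append(
                SomaticEvent(
                    gene=call.gene,
                    kind=EventKind.single_mutation,
                    inactivating=is_inactivating(call),
                    source_call=call,
                )
            )
    for res in loh_results:
        if res.gene in mmr_genes and res.loh_flag:
            events.append(SomaticEvent(gene=res.gene, kind=EventKind.loh))
    return events


@dataclass
class SecondHit:
    """Whether a somatic second hit exists in the gene carrying the VUS."""

    present: bool
    kinds: list = field(default_factory=list)  # list[EventKind], one per event


def detect_second_hit(vus: GermlineVariant | str, events: Sequence[SomaticEvent]) -> SecondHit:
    """Knudson second hit: any inactivating somatic event in the VUS gene."""
    gene = vus.gene if isinstance(vus, GermlineVariant) else vus
    kinds = [e.kind for e in events if e.gene == gene and e.inactivating]
    return SecondHit(present=bool(kinds), kinds=kinds)


def detect_double_somatic(events: Sequence[SomaticEvent]) -> list[str]:
    """Genes with two or more inactivating somatic events (LOH counts once).

    Two inactivating events in one gene can produce biallelic inactivation
    without any germline contribution ("double somatic").  Returned in
    fixed gene order MLH1, MSH2, MSH6, PMS2.
    """
    return [
        gene
        for gene in MMR_GENES
        if sum(1 for e in events if e.gene == gene and e.inactivating) >= 2
    ]


def tumor_mutation_burden(filtered_calls: Sequence[SomaticCall], cfg: FilterConfig) -> float:
    """Somatic mutations per megabase of capture target."""
    if cfg.target_megabases <= 0:
        raise ValueError("target_megabases must be positive")
    return len(filtered_calls) / cfg.target_megabases
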