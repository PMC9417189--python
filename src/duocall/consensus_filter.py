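"""The filter cascade and cross-caller consensus.

Each caller's call set passes through the same predicates — record-level
quality, germline subtraction, sequence context, population frequency — and
survivors of both callers are intersected on exact (contig, pos, ref, alt)
keys.  Every predicate is always evaluated so a failing call carries the full
set of reasons; the verdict is order-independent by construction.

Threshold boundaries are inclusive exactly as worded: quality >= 10, at least
4 alt-supporting reads, at least 10X normal coverage; the population filter
removes strictly above 0.1% MAF.
"""
from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .caller_io import (
    AnnotationRecord,
    DepthTrack,
    PopulationFrequencyTable,
    SomaticCall,
    VariantKey,
)
from .errors import InputError
from .reference_context import (
    HomopolymerRun,
    IntervalSet,
    in_interval_set,
    is_homopolymer_proximal,
)

__all__ = [
    "FilterConfig",
    "FilterReason",
    "FilterOutcome",
    "ConsensusVariant",
    "apply_record_filters",
    "apply_site_filters",
    "apply_population_filter",
    "subtract_germline",
    "run_cascade",
    "intersect_callsets",
    "attrition_summary",
    "merge_outcomes",
    "write_consensus_tsv",
    "write_consensus_vcf",
    "write_audit_tsv",
    "write_attrition_tsv",
]


class FilterReason(str, Enum):
    FAIL_FILTER_FIELD = "FAIL_FILTER_FIELD"
    FAIL_QUAL = "FAIL_QUAL"
    FAIL_ALT_READS = "FAIL_ALT_READS"
    FAIL_NORMAL_COVERAGE = "FAIL_NORMAL_COVERAGE"
    FAIL_HOMOPOLYMER = "FAIL_HOMOPOLYMER"
    FAIL_REPEAT = "FAIL_REPEAT"
    FAIL_POPULATION_MAF = "FAIL_POPULATION_MAF"
    FAIL_GERMLINE_MATCH = "FAIL_GERMLINE_MATCH"
    FAIL_NON_SNV = "FAIL_NON_SNV"


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 10.0
    min_alt_reads: int = 4
    min_normal_depth: int = 10
    homopolymer_min_run: int = 4
    homopolymer_distance: int = 1
    max_population_maf: float = 0.001
    require_pass: bool = True
    snv_only: bool = False
    population_match_allele: bool = True  # False: position-only "colocated" mode

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_alt_reads, self.min_normal_depth) < 0:
            raise InputError("thresholds must be >= 0")
        if not 0.0 <= self.max_population_maf <= 1.0:
            raise InputError("max_population_maf must be in [0,1]")


@dataclass(frozen=True)
class FilterOutcome:
    call: SomaticCall
    reasons: frozenset[FilterReason]

    @property
    def passed(self) -> bool:
        return not self.reasons


def merge_outcomes(*outcomes: FilterOutcome) -> FilterOutcome:
    """Union the reasons of several outcomes for the same call."""
    call = outcomes[0].call
    reasons: set[FilterReason] = set()
    for o in outcomes:
        if o.call.key != call.key:
            raise InputError("cannot merge outcomes of different calls")
        reasons |= o.reasons
    return FilterOutcome(call, frozenset(reasons))


def apply_record_filters(call: SomaticCall, cfg: FilterConfig) -> FilterOutcome:
    """Per-record filters: FILTER field, unified quality, alt-read support."""
    reasons = set()
    if cfg.require_pass and call.filter_status != "PASS":
        reasons.add(FilterReason.FAIL_FILTER_FIELD)
    if call.qual_score < cfg.min_qual:
        reasons.add(FilterReason.FAIL_QUAL)
    if call.tumor_alt_depth < cfg.min_alt_reads:
        reasons.add(FilterReason.FAIL_ALT_READS)
    if cfg.snv_only and not call.is_snv:
        reasons.add(FilterReason.FAIL_NON_SNV)
    return FilterOutcome(call, frozenset(reasons))


def resolve_normal_depth(call: SomaticCall, track: DepthTrack | None) -> int:
    """Normal-sample depth at the call site.

    The dedicated depth track wins over the caller-reported normal DP when
    both are available; with neither, depth is 0 (conservatively failing).
    """
    if track is not None:
        return track.depth_at(call.contig, call.pos1)
    if call.normal_depth is not None:
        return call.normal_depth
    return 0


def apply_site_filters(
    call: SomaticCall,
    runs: Sequence[HomopolymerRun],
    repeats: IntervalSet,
    normal_depth_source: DepthTrack | None,
    cfg: FilterConfig,
) -> FilterOutcome:
    """Sequence-context and normal-coverage filters."""
    reasons = set()
    if resolve_normal_depth(call, normal_depth_source) < cfg.min_normal_depth:
        reasons.add(FilterReason.FAIL_NORMAL_COVERAGE)
    if is_homopolymer_proximal(
        call.contig, call.pos1, list(runs), distance=cfg.homopolymer_distance
    ):
        reasons.add(FilterReason.FAIL_HOMOPOLYMER)
    if in_interval_set(call.contig, call.pos1, repeats):
        reasons.add(FilterReason.FAIL_REPEAT)
    return FilterOutcome(call, frozenset(reasons))


def apply_population_filter(
    call: SomaticCall, freqs: PopulationFrequencyTable | None, cfg: FilterConfig
) -> FilterOutcome:
    """Remove calls whose population MAF is strictly above the threshold."""
    reasons = set()
    if freqs is not None:
        if cfg.population_match_allele:
            maf = freqs.get(call.key)
        else:
            maf = freqs.max_at_position(call.contig, call.pos1)
        if maf is not None and maf > cfg.max_population_maf:
            reasons.add(FilterReason.FAIL_POPULATION_MAF)
    return FilterOutcome(call, frozenset(reasons))


def subtract_germline(
    calls: Iterable[SomaticCall], germline_keys: set[VariantKey]
) -> list[FilterOutcome]:
    """Flag calls whose exact variant key appears in the germline call set."""
    out = []
    for call in calls:
        reasons = (
            frozenset({FilterReason.FAIL_GERMLINE_MATCH})
            if call.key in germline_keys
            else frozenset()
        )
        out.append(FilterOutcome(call, reasons))
    return out


def run_cascade(
    calls: Sequence[SomaticCall],
    *,
    runs: Sequence[HomopolymerRun],
    repeats: IntervalSet,
    depth_track: DepthTrack | None,
    freqs: PopulationFrequencyTable | None,
    germline_keys: set[VariantKey] | None,
    cfg: FilterConfig,
) -> tuple[list[SomaticCall], list[FilterOutcome]]:
    """Apply every predicate to every call; a call survives iff all pass.

    Returns (survivors, audit) where the audit holds one outcome per input
    call with the union of all failing reasons.
    """
    germline_keys = germline_keys or set()
    germline_outcomes = subtract_germline(calls, germline_keys)
    audit: list[FilterOutcome] = []
    survivors: list[SomaticCall] = []
    for call, germ in zip(calls, germline_outcomes):
        outcome = merge_outcomes(
            apply_record_filters(call, cfg),
            germ,
            apply_site_filters(call, runs, repeats, depth_track, cfg),
            apply_population_filter(call, freqs, cfg),
        )
        audit.append(outcome)
        if outcome.passed:
            survivors.append(call)
    return survivors, audit


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant confirmed by both callers after filtering."""

    sample_id: str
    contig: str
    pos1: int
    ref_allele: str
    alt_allele: str
    evidence_a: SomaticCall
    evidence_b: SomaticCall
    allele_fraction: float | None
    annotation: AnnotationRecord | None = None

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


def intersect_callsets(
    survivors_a: Sequence[SomaticCall],
    survivors_b: Sequence[SomaticCall],
    af_source: str = "A",
) -> list[ConsensusVariant]:
    """One ConsensusVariant per variant key surviving in both callers.

    The allele fraction comes from the ``af_source`` caller's read counts,
    falling back to the other caller when that evidence lacks depth.
    """
    if af_source not in ("A", "B"):
        raise InputError(f"af_source must be A or B, got {af_source!r}")

    def keyed(calls: Sequence[SomaticCall], label: str) -> dict[VariantKey, SomaticCall]:
        out: dict[VariantKey, SomaticCall] = {}
        for c in calls:
            if c.key in out:
                raise InputError(f"duplicate key {c.key} in caller-{label} survivors")
            out[c.key] = c
        return out

    a_by_key = keyed(survivors_a, "A")
    b_by_key = keyed(survivors_b, "B")
    sample_ids = {c.sample_id for c in list(survivors_a) + list(survivors_b)}
    if len(sample_ids) > 1:
        raise InputError(f"call sets span multiple samples: {sorted(sample_ids)}")
    consensus = []
    for key in sorted(set(a_by_key) & set(b_by_key)):
        ev_a, ev_b = a_by_key[key], b_by_key[key]
        primary, fallback = (ev_a, ev_b) if af_source == "A" else (ev_b, ev_a)
        af = primary.allele_fraction
        if af is None:
            af = fallback.allele_fraction
        consensus.append(
            ConsensusVariant(
                sample_id=ev_a.sample_id,
                contig=key[0],
                pos1=key[1],
                ref_allele=key[2],
                alt_allele=key[3],
                evidence_a=ev_a,
                evidence_b=ev_b,
                allele_fraction=af,
            )
        )
    return consensus


def attrition_summary(audit: Sequence[FilterOutcome]) -> dict[str, int]:
    """Counts: input, surviving, and per-reason failures (a call may carry several)."""
    counts: Counter[str] = Counter()
    counts["n_in"] = len(audit)
    counts["n_out"] = sum(1 for o in audit if o.passed)
    for o in audit:
        for reason in o.reasons:
            counts[reason.value] += 1
    return dict(counts)


def write_consensus_tsv(
    variants: Sequence[ConsensusVariant], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "sample",
                "contig",
                "pos",
                "ref",
                "alt",
                "allele_fraction",
                "gene",
                "consequence",
                "cadd_phred",
                "pop_freq",
            ]
        )
        for v in variants:
            ann = v.annotation
            w.writerow(
                [
                    v.sample_id,
                    v.contig,
                    v.pos1,
                    v.ref_allele,
                    v.alt_allele,
                    "" if v.allele_fraction is None else f"{v.allele_fraction:.6g}",
                    ann.gene_symbol if ann and ann.gene_symbol else "",
                    ann.consequence if ann else "",
                    "" if not ann or ann.cadd_phred is None else f"{ann.cadd_phred:g}",
                    "" if not ann or ann.population_freq is None else f"{ann.population_freq:g}",
                ]
            )


def write_consensus_vcf(
    variants: Sequence[ConsensusVariant],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Tumor alternate allele fraction">',
        '##INFO=<ID=DPA,Number=1,Type=Integer,Description="Caller A tumor depth">',
        '##INFO=<ID=DPB,Number=1,Type=Integer,Description="Caller B tumor depth">',
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.contig, v.pos1, v.ref_allele, v.alt_allele)):
        af = "." if v.allele_fraction is None else f"{v.allele_fraction:.4f}"
        info = (
            f"AF={af};DPA={v.evidence_a.tumor_total_depth};"
            f"DPB={v.evidence_b.tumor_total_depth}"
        )
        lines.append(
            "\t".join(
                [
                    v.contig,
                    str(v.pos1),
                    v.evidence_a.dbsnp_id or ".",
                    v.ref_allele,
                    v.alt_allele,
                    ".",
                    "PASS",
                    info,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_audit_tsv(
    audits: Sequence[tuple[str, Sequence[FilterOutcome]]], path: str | Path
) -> None:
    """Write audit trails as TSV; ``audits`` pairs a caller label with outcomes."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "caller", "contig", "pos", "ref", "alt", "passed", "reasons"])
        for caller, outcomes in audits:
            for o in outcomes:
                c = o.call
                w.writerow(
                    [
                        c.sample_id,
                        caller,
                        c.contig,
                        c.pos1,
                        c.ref_allele,
                        c.alt_allele,
                        int(o.passed),
                        ",".join(sorted(r.value for r in o.reasons)),
                    ]
                )


def write_attrition_tsv(
    rows: Sequence[tuple[str, str, dict[str, int]]], path: str | Path
) -> None:
    """Rows of (sample, caller, attrition counts)."""
    reasons = [r.value for r in FilterReason]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "caller", "n_in", "n_out"] + reasons)
        for sample, caller, counts in rows:
            w.writerow(
                [sample, caller, counts.get("n_in", 0), counts.get("n_out", 0)]
                + [counts.get(r, 0) for r in reasons]
            )
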