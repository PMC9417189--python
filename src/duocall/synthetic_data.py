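"""Self-contained synthetic tumor-normal cohort generator and truth-based evaluator.

Generates a reference with planted homopolymer runs, repeat and target masks,
per-sample truth variants (clonal/subclonal somatic, germline, population-SNP
leaks and one artifact class per filter under test), and writes the evidence
files every other module consumes: two caller-dialect somatic VCFs, a germline
VCF, a normal-depth track, a population-frequency TSV, an annotation TSV and a
truth manifest.  The whole bundle is a pure function of the configuration
(seed included).

Depth model: per-site tumor depth ~ Poisson(mean_depth), alt depth ~
Binomial(depth, designed AF); with ``binomial_noise=False`` the alt depth is
round(depth x AF), which makes pipeline output exactly equal to the
CONSENSUS-fate truth set (the strongest end-to-end oracle).  For
CONSENSUS-fate records the site depth is raised to the minimum at which the
designed AF yields at least the alt-read threshold, so the designed fate is
consistent with the designed evidence.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .caller_io import SomaticCall, VariantKey, write_dialect_a_vcf
from .consensus_filter import FilterReason
from .errors import ConfigError, InputError
from .reference_context import (
    GenomicInterval,
    HomopolymerRun,
    IntervalSet,
    ReferenceSet,
    write_fasta,
)

__all__ = [
    "SimulationConfig",
    "TruthClass",
    "TruthVariant",
    "SimBundle",
    "EXPECTED_FATE",
    "EXPECTED_REASON",
    "generate_reference",
    "generate_population",
    "generate_truth",
    "simulate_evidence_and_write",
    "read_truth_manifest",
    "evaluate_against_truth",
    "EvaluationResult",
]

_BASES = "ACGT"


class TruthClass(str, Enum):
    SOMATIC_CLONAL = "SOMATIC_CLONAL"
    SOMATIC_SUBCLONAL = "SOMATIC_SUBCLONAL"
    GERMLINE = "GERMLINE"
    COMMON_SNP_LEAK = "COMMON_SNP_LEAK"
    ARTIFACT_HOMOPOLYMER = "ARTIFACT_HOMOPOLYMER"
    ARTIFACT_REPEAT = "ARTIFACT_REPEAT"
    ARTIFACT_LOW_QUAL = "ARTIFACT_LOW_QUAL"
    ARTIFACT_LOW_ALT_READS = "ARTIFACT_LOW_ALT_READS"
    ARTIFACT_CALLER_UNIQUE_A = "ARTIFACT_CALLER_UNIQUE_A"
    ARTIFACT_CALLER_UNIQUE_B = "ARTIFACT_CALLER_UNIQUE_B"
    ARTIFACT_LOW_NORMAL_DEPTH = "ARTIFACT_LOW_NORMAL_DEPTH"


# Fate is a pure function of class, mirroring the filter each class targets.
EXPECTED_FATE: dict[TruthClass, str] = {
    TruthClass.SOMATIC_CLONAL: "CONSENSUS",
    TruthClass.SOMATIC_SUBCLONAL: "CONSENSUS",
    TruthClass.GERMLINE: "FILTERED",
    TruthClass.COMMON_SNP_LEAK: "FILTERED",
    TruthClass.ARTIFACT_HOMOPOLYMER: "FILTERED",
    TruthClass.ARTIFACT_REPEAT: "FILTERED",
    TruthClass.ARTIFACT_LOW_QUAL: "FILTERED",
    TruthClass.ARTIFACT_LOW_ALT_READS: "FILTERED",
    TruthClass.ARTIFACT_CALLER_UNIQUE_A: "CALLER_UNIQUE",
    TruthClass.ARTIFACT_CALLER_UNIQUE_B: "CALLER_UNIQUE",
    TruthClass.ARTIFACT_LOW_NORMAL_DEPTH: "FILTERED",
}

EXPECTED_REASON: dict[TruthClass, FilterReason] = {
    TruthClass.GERMLINE: FilterReason.FAIL_GERMLINE_MATCH,
    TruthClass.COMMON_SNP_LEAK: FilterReason.FAIL_POPULATION_MAF,
    TruthClass.ARTIFACT_HOMOPOLYMER: FilterReason.FAIL_HOMOPOLYMER,
    TruthClass.ARTIFACT_REPEAT: FilterReason.FAIL_REPEAT,
    TruthClass.ARTIFACT_LOW_QUAL: FilterReason.FAIL_QUAL,
    TruthClass.ARTIFACT_LOW_ALT_READS: FilterReason.FAIL_ALT_READS,
    TruthClass.ARTIFACT_LOW_NORMAL_DEPTH: FilterReason.FAIL_NORMAL_COVERAGE,
}

_DEFAULT_CLASS_COUNTS = {
    TruthClass.SOMATIC_CLONAL: 10,
    TruthClass.SOMATIC_SUBCLONAL: 6,
    TruthClass.GERMLINE: 6,
    TruthClass.COMMON_SNP_LEAK: 2,
    TruthClass.ARTIFACT_HOMOPOLYMER: 2,
    TruthClass.ARTIFACT_REPEAT: 2,
    TruthClass.ARTIFACT_LOW_QUAL: 2,
    TruthClass.ARTIFACT_LOW_ALT_READS: 2,
    TruthClass.ARTIFACT_CALLER_UNIQUE_A: 1,
    TruthClass.ARTIFACT_CALLER_UNIQUE_B: 1,
    TruthClass.ARTIFACT_LOW_NORMAL_DEPTH: 2,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_samples: int = 15
    contig_lengths: tuple[int, ...] = (60_000, 40_000)
    n_homopolymers: int = 30
    homopolymer_length_range: tuple[int, int] = (4, 8)
    repeat_fraction: float = 0.08
    n_common_snps: int = 30
    common_snp_maf_range: tuple[float, float] = (0.002, 0.05)
    class_counts: Mapping[TruthClass, int] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_COUNTS)
    )
    mean_depth: float = 50.0
    clonal_af_range: tuple[float, float] = (0.30, 0.60)
    subclonal_af_range: tuple[float, float] = (0.05, 0.19)
    binomial_noise: bool = True
    shared_variant_samples: int = 3  # plant one shared clonal variant in this many samples
    nonpass_artifact_fraction: float = 0.0
    min_homopolymer_run: int = 4
    min_alt_reads: int = 4  # evidence floor used for CONSENSUS-fate depth guarantee

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if any(n < 0 for n in self.class_counts.values()):
            raise ConfigError("class counts must be >= 0")
        for lo, hi in (self.clonal_af_range, self.subclonal_af_range):
            if not (0.0 < lo <= hi < 1.0):
                raise ConfigError("AF ranges must lie within (0,1)")
        if self.subclonal_af_range[1] >= 0.20:
            raise ConfigError("subclonal AF range must lie entirely below 0.20")
        if self.common_snp_maf_range[0] <= 0.001:
            raise ConfigError("common-SNP MAF range must lie above the 0.1% threshold")
        if not 0.0 <= self.repeat_fraction < 0.5:
            raise ConfigError("repeat_fraction must be in [0, 0.5)")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def counts(self) -> dict[TruthClass, int]:
        merged = dict(_DEFAULT_CLASS_COUNTS)
        merged.update({TruthClass(k): int(v) for k, v in self.class_counts.items()})
        return merged


@dataclass(frozen=True)
class TruthVariant:
    sample_id: str
    contig: str
    pos1: int
    ref: str
    alt: str
    truth_class: TruthClass
    designed_af: float

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref, self.alt)

    @property
    def expected_fate(self) -> str:
        return EXPECTED_FATE[self.truth_class]


@dataclass(frozen=True)
class PopulationSite:
    contig: str
    pos1: int
    ref: str
    alt: str
    maf: float

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref, self.alt)


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def _runfree_sequence(rng: np.random.Generator, length: int, max_run: int) -> list[str]:
    """Random A/C/G/T sequence with no homopolymer run reaching ``max_run``."""
    draws = rng.integers(0, 4, size=length)
    alts = rng.integers(1, 4, size=length)
    seq: list[int] = []
    run = 0
    for i in range(length):
        b = int(draws[i])
        if run == max_run - 1 and seq and b == seq[-1]:
            b = (b + int(alts[i])) % 4
        if seq and b == seq[-1]:
            run += 1
        else:
            run = 1
        seq.append(b)
    return [_BASES[b] for b in seq]


def generate_reference(
    cfg: SimulationConfig,
) -> tuple[ReferenceSet, list[HomopolymerRun], IntervalSet, IntervalSet]:
    """Reference with planted homopolymer runs, a repeat mask covering about
    ``repeat_fraction`` of the genome, and targets covering the remainder."""
    rng = _rng(cfg, 11)
    contigs: dict[str, list[str]] = {}
    runs: list[HomopolymerRun] = []
    total_len = sum(cfg.contig_lengths)
    lo, hi = cfg.homopolymer_length_range
    if lo < cfg.min_homopolymer_run:
        raise ConfigError("planted run length below the minimum homopolymer run")
    run_zones: dict[str, list[tuple[int, int]]] = {}

    for ci, length in enumerate(cfg.contig_lengths):
        name = f"c{ci + 1}"
        seq = _runfree_sequence(rng, length, cfg.min_homopolymer_run)
        n_runs = round(cfg.n_homopolymers * length / total_len)
        if ci == len(cfg.contig_lengths) - 1:
            n_runs = cfg.n_homopolymers - sum(len(v) for v in run_zones.values())
        zones: list[tuple[int, int]] = []
        if n_runs * (hi + 8) > length:
            raise ConfigError(
                f"cannot place {n_runs} homopolymer runs on a {length} bp contig"
            )
        attempts = 0
        while len(zones) < n_runs:
            attempts += 1
            if attempts > 1000 * max(n_runs, 1):
                raise ConfigError("homopolymer placement infeasible")
            run_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(2, length - run_len - 2))  # keep flanks in bounds
            if any(start - 4 < e and s < start + run_len + 4 for s, e in zones):
                continue
            base_i = int(rng.integers(0, 4))
            base = _BASES[base_i]
            for j in range(start, start + run_len):
                seq[j] = base
            for flank in (start - 1, start + run_len):
                neighbors = {base}
                if flank - 1 >= 0 and flank - 1 not in range(start, start + run_len):
                    neighbors.add(seq[flank - 1])
                if flank + 1 < length and flank + 1 not in range(start, start + run_len):
                    neighbors.add(seq[flank + 1])
                allowed = [b for b in _BASES if b not in neighbors]
                seq[flank] = allowed[int(rng.integers(0, len(allowed)))]
            zones.append((start, start + run_len))
            runs.append(HomopolymerRun(name, start + 1, start + run_len, base))
        run_zones[name] = zones
        contigs[name] = seq

    ref = ReferenceSet({name: "".join(seq) for name, seq in contigs.items()})
    runs.sort(key=lambda r: (r.contig, r.start1))

    # repeat mask: random intervals away from (planted run +- 2) zones
    repeat_ivs: list[GenomicInterval] = []
    for ci, length in enumerate(cfg.contig_lengths):
        name = f"c{ci + 1}"
        forbidden = [(max(0, s - 3), min(length, e + 3)) for s, e in run_zones[name]]
        want = int(cfg.repeat_fraction * length)
        got = 0
        chosen: list[tuple[int, int]] = []
        attempts = 0
        while got < want:
            attempts += 1
            if attempts > 10_000:
                raise ConfigError("repeat placement infeasible")
            span = int(rng.integers(200, 601))
            start = int(rng.integers(0, max(1, length - span)))
            iv = (start, start + span)
            if any(iv[0] - 2 < e and s < iv[1] + 2 for s, e in forbidden):
                continue
            if any(iv[0] - 2 < e and s < iv[1] + 2 for s, e in chosen):
                continue
            chosen.append(iv)
            got += span
        repeat_ivs.extend(GenomicInterval(name, s, e) for s, e in chosen)
    repeats = IntervalSet(repeat_ivs)
    targets = repeats.complement(ref.lengths)
    return ref, runs, repeats, targets


def _proximal_zone(runs: Sequence[HomopolymerRun], distance: int = 1) -> dict[str, set[int]]:
    zone: dict[str, set[int]] = {}
    for r in runs:
        zone.setdefault(r.contig, set()).update(
            range(r.start1 - distance, r.end1 + distance + 1)
        )
    return zone


def _pick_clean_position(
    rng: np.random.Generator,
    ref: ReferenceSet,
    repeats: IntervalSet,
    proximal: dict[str, set[int]],
    used: set[tuple[str, int]],
) -> tuple[str, int]:
    names = ref.names
    lengths = ref.lengths
    for _ in range(100_000):
        contig = names[int(rng.integers(0, len(names)))]
        pos1 = int(rng.integers(1, lengths[contig] + 1))
        if (contig, pos1) in used:
            continue
        if pos1 in proximal.get(contig, ()):
            continue
        if repeats.contains(contig, pos1):
            continue
        if ref.base_at(contig, pos1) == "N":
            continue
        used.add((contig, pos1))
        return contig, pos1
    raise ConfigError("clean variant placement infeasible")


def _alt_base(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in _BASES if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def generate_population(
    cfg: SimulationConfig,
    ref: ReferenceSet,
    runs: Sequence[HomopolymerRun],
    repeats: IntervalSet,
) -> list[PopulationSite]:
    """Common-SNP sites (MAF above the 0.1% filter threshold) at clean positions."""
    rng = _rng(cfg, 12)
    proximal = _proximal_zone(runs)
    used: set[tuple[str, int]] = set()
    lo, hi = cfg.common_snp_maf_range
    sites = []
    for _ in range(cfg.n_common_snps):
        contig, pos1 = _pick_clean_position(rng, ref, repeats, proximal, used)
        ref_base = ref.base_at(contig, pos1)
        sites.append(
            PopulationSite(
                contig,
                pos1,
                ref_base,
                _alt_base(rng, ref_base),
                float(rng.uniform(lo, hi)),
            )
        )
    sites.sort(key=lambda s: (s.contig, s.pos1))
    return sites


def generate_truth(
    cfg: SimulationConfig,
    ref: ReferenceSet,
    runs: Sequence[HomopolymerRun],
    repeats: IntervalSet,
    population: Sequence[PopulationSite],
) -> list[TruthVariant]:
    """Per-sample truth records with class-determined placement and AF."""
    rng = _rng(cfg, 13)
    proximal = _proximal_zone(runs)
    # positions reserved cohort-wide: population sites and every placed variant
    used: set[tuple[str, int]] = {(s.contig, s.pos1) for s in population}
    counts = cfg.counts()
    truths: list[TruthVariant] = []

    def uniform(r: tuple[float, float]) -> float:
        return float(rng.uniform(r[0], r[1]))

    # one shared clonal variant in the first k samples, for recurrence tests
    shared: tuple[str, int, str, str] | None = None
    k_shared = min(cfg.shared_variant_samples, cfg.n_samples)
    if k_shared >= 2 and counts[TruthClass.SOMATIC_CLONAL] > 0:
        contig, pos1 = _pick_clean_position(rng, ref, repeats, proximal, used)
        ref_base = ref.base_at(contig, pos1)
        shared = (contig, pos1, ref_base, _alt_base(rng, ref_base))

    leak_pool = [s for s in population if s.maf > 0.001]

    for si, sample_id in enumerate(cfg.sample_ids):
        n_leaks = counts[TruthClass.COMMON_SNP_LEAK]
        if n_leaks > len(leak_pool):
            raise ConfigError("not enough common-SNP sites for the configured leaks")
        leak_sites = (
            [leak_pool[int(i)] for i in rng.choice(len(leak_pool), size=n_leaks, replace=False)]
            if n_leaks
            else []
        )
        leak_iter = iter(leak_sites)
        if shared is not None and si < k_shared:
            truths.append(
                TruthVariant(
                    sample_id,
                    *shared,
                    TruthClass.SOMATIC_CLONAL,
                    uniform(cfg.clonal_af_range),
                )
            )
        for tclass, n in counts.items():
            for _ in range(n):
                if tclass is TruthClass.COMMON_SNP_LEAK:
                    site = next(leak_iter)
                    truths.append(
                        TruthVariant(
                            sample_id,
                            site.contig,
                            site.pos1,
                            site.ref,
                            site.alt,
                            tclass,
                            uniform(cfg.clonal_af_range),
                        )
                    )
                    continue
                if tclass is TruthClass.ARTIFACT_HOMOPOLYMER:
                    if not runs:
                        raise ConfigError("homopolymer artifacts need planted runs")
                    placed = False
                    for _attempt in range(1000):
                        run = runs[int(rng.integers(0, len(runs)))]
                        pos1 = int(rng.integers(run.start1 - 1, run.end1 + 2))
                        if pos1 < 1 or pos1 > ref.length(run.contig):
                            continue
                        if (run.contig, pos1) in used:
                            continue
                        used.add((run.contig, pos1))
                        contig = run.contig
                        placed = True
                        break
                    if not placed:
                        raise ConfigError("homopolymer artifact placement infeasible")
                elif tclass is TruthClass.ARTIFACT_REPEAT:
                    ivs = list(repeats)
                    if not ivs:
                        raise ConfigError("repeat artifacts need repeat intervals")
                    placed = False
                    for _attempt in range(1000):
                        iv = ivs[int(rng.integers(0, len(ivs)))]
                        pos1 = int(rng.integers(iv.start + 1, iv.end + 1))
                        if (iv.contig, pos1) in used:
                            continue
                        used.add((iv.contig, pos1))
                        contig = iv.contig
                        placed = True
                        break
                    if not placed:
                        raise ConfigError("repeat artifact placement infeasible")
                else:
                    contig, pos1 = _pick_clean_position(rng, ref, repeats, proximal, used)

                if tclass is TruthClass.SOMATIC_SUBCLONAL:
                    af = uniform(cfg.subclonal_af_range)
                elif tclass is TruthClass.GERMLINE:
                    af = 0.5
                elif tclass is TruthClass.ARTIFACT_LOW_ALT_READS:
                    af = float(rng.uniform(0.01, 0.05))
                else:
                    af = uniform(cfg.clonal_af_range)
                ref_base = ref.base_at(contig, pos1)
                truths.append(
                    TruthVariant(
                        sample_id,
                        contig,
                        pos1,
                        ref_base,
                        _alt_base(rng, ref_base),
                        tclass,
                        af,
                    )
                )
    return truths


@dataclass
class SimBundle:
    """Paths of everything a simulated cohort run needs."""

    root: Path
    reference: Path
    repeats_bed: Path
    targets_bed: Path
    population: Path
    annotations: Path
    truth_manifest: Path
    sample_sheet: Path
    sample_files: dict[str, dict[str, Path]]


_CONSEQUENCE_POOL = [
    ("missense_variant", 0.28),
    ("synonymous_variant", 0.14),
    ("intron_variant", 0.30),
    ("3_prime_utr_variant", 0.05),
    ("5_prime_utr_variant", 0.04),
    ("non_coding_transcript_exon_variant", 0.05),
    ("downstream_gene_variant", 0.07),
    ("upstream_gene_variant", 0.04),
    ("splice_region_variant", 0.03),
]


def _consensus_depth_floor(cfg: SimulationConfig, af: float) -> int:
    # smallest depth at which round(depth * af) >= the alt-read threshold
    return math.ceil(cfg.min_alt_reads / af)


def simulate_evidence_and_write(
    cfg: SimulationConfig,
    ref: ReferenceSet,
    runs: Sequence[HomopolymerRun],
    repeats: IntervalSet,
    targets: IntervalSet,
    population: Sequence[PopulationSite],
    truths: Sequence[TruthVariant],
    outdir: str | Path,
) -> SimBundle:
    """Write the full file bundle; deterministic given the configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_path = outdir / "reference.fa"
    write_fasta(ref, ref_path)
    repeats_path = outdir / "repeats.bed"
    repeats.to_bed(repeats_path)
    targets_path = outdir / "targets.bed"
    targets.to_bed(targets_path)

    pop_path = outdir / "population.tsv"
    with open(pop_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "pos1", "ref", "alt", "maf"])
        for s in population:
            w.writerow([s.contig, s.pos1, s.ref, s.alt, f"{s.maf:.6f}"])

    # annotations for every distinct truth key; genes tile the genome in 2 kb bins
    rng_ann = _rng(cfg, 14)
    pop_maf = {s.key: s.maf for s in population}
    contig_index = {name: i for i, name in enumerate(ref.names)}
    labels = [c for c, _ in _CONSEQUENCE_POOL]
    weights = np.array([wgt for _, wgt in _CONSEQUENCE_POOL])
    weights = weights / weights.sum()
    ann_path = outdir / "annotations.tsv"
    keys = sorted({t.key for t in truths}, key=lambda k: (contig_index[k[0]], k[1], k[2], k[3]))
    with open(ann_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "pos", "ref", "alt", "gene", "consequence", "cadd_phred", "pop_freq"])
        for key in keys:
            contig, pos1, r, a = key
            tile = contig_index[contig] * 1000 + (pos1 - 1) // 2000
            gene = f"G{tile:05d}"
            consequence = labels[int(rng_ann.choice(len(labels), p=weights))]
            cadd = float(rng_ann.uniform(0.0, 45.0))
            w.writerow(
                [contig, pos1, r, a, gene, consequence, f"{cadd:.2f}", f"{pop_maf.get(key, 0.0):.6f}"]
            )

    truth_path = outdir / "truth_manifest.tsv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "contig", "pos", "ref", "alt", "class", "designed_af", "expected_fate"])
        for t in truths:
            w.writerow(
                [
                    t.sample_id,
                    t.contig,
                    t.pos1,
                    t.ref,
                    t.alt,
                    t.truth_class.value,
                    f"{t.designed_af:.4f}",
                    t.expected_fate,
                ]
            )

    by_sample: dict[str, list[TruthVariant]] = {s: [] for s in cfg.sample_ids}
    for t in truths:
        by_sample[t.sample_id].append(t)

    sample_files: dict[str, dict[str, Path]] = {}
    for si, sample_id in enumerate(cfg.sample_ids):
        rng = _rng(cfg, 15, si)
        records = sorted(
            by_sample[sample_id], key=lambda t: (contig_index[t.contig], t.pos1, t.ref, t.alt)
        )
        calls_a: list[SomaticCall] = []
        rows_b: list[dict] = []
        germline_rows: list[TruthVariant] = []
        low_normal_sites: dict[str, dict[int, int]] = {}
        for t in records:
            depth = max(1, int(rng.poisson(cfg.mean_depth)))
            if t.expected_fate == "CONSENSUS":
                depth = max(depth, _consensus_depth_floor(cfg, t.designed_af))
            if t.truth_class is TruthClass.ARTIFACT_LOW_ALT_READS:
                alt_depth = int(rng.integers(1, cfg.min_alt_reads))
                depth = max(depth, alt_depth)
            elif cfg.binomial_noise:
                alt_depth = int(rng.binomial(depth, t.designed_af))
            else:
                alt_depth = int(round(depth * t.designed_af))
            alt_depth = min(alt_depth, depth)

            if t.truth_class is TruthClass.ARTIFACT_LOW_QUAL:
                qual_a = float(rng.uniform(0.5, 9.4))
                score_b = float(rng.uniform(0.5, 9.4))
            else:
                qual_a = float(rng.uniform(25.0, 60.0))
                score_b = float(rng.uniform(15.0, 40.0))

            filter_status = "PASS"
            if (
                t.truth_class.value.startswith("ARTIFACT")
                and cfg.nonpass_artifact_fraction > 0
                and rng.uniform() < cfg.nonpass_artifact_fraction
            ):
                filter_status = "LowSupport"

            if t.truth_class is TruthClass.ARTIFACT_LOW_NORMAL_DEPTH:
                normal_depth = int(rng.integers(0, 10))
                low_normal_sites.setdefault(t.contig, {})[t.pos1] = normal_depth
            else:
                normal_depth = max(10, int(rng.poisson(cfg.mean_depth)))

            if t.truth_class is TruthClass.GERMLINE:
                germline_rows.append(t)

            if t.truth_class is not TruthClass.ARTIFACT_CALLER_UNIQUE_B:
                calls_a.append(
                    SomaticCall(
                        sample_id=sample_id,
                        caller_id="A",
                        contig=t.contig,
                        pos1=t.pos1,
                        ref_allele=t.ref,
                        alt_allele=t.alt,
                        filter_status=filter_status,
                        qual_score=round(qual_a, 2),
                        tumor_alt_depth=alt_depth,
                        tumor_total_depth=depth,
                        normal_depth=normal_depth,
                    )
                )
            if t.truth_class is not TruthClass.ARTIFACT_CALLER_UNIQUE_A:
                rows_b.append(
                    dict(
                        contig=t.contig,
                        pos1=t.pos1,
                        ref=t.ref,
                        alt=t.alt,
                        filter_status="LowEVS" if filter_status != "PASS" else "PASS",
                        score=round(score_b, 2),
                        depth=depth,
                        alt_depth=alt_depth,
                        normal_depth=normal_depth,
                    )
                )

        files: dict[str, Path] = {}
        files["vcf_a"] = outdir / f"{sample_id}.callerA.vcf"
        write_dialect_a_vcf(calls_a, files["vcf_a"], ref.lengths, sample_id)
        files["vcf_b"] = outdir / f"{sample_id}.callerB.vcf"
        _write_dialect_b_vcf(rows_b, files["vcf_b"], ref.lengths)
        files["germline_vcf"] = outdir / f"{sample_id}.germline.vcf"
        _write_germline_vcf(germline_rows, files["germline_vcf"], ref.lengths, sample_id)
        files["depth_track"] = outdir / f"{sample_id}.normal_depth.tsv"
        _write_depth_track(
            files["depth_track"], ref.lengths, low_normal_sites, rng, cfg.mean_depth
        )
        sample_files[sample_id] = files

    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "vcf_a", "vcf_b", "germline_vcf", "depth_track"])
        for sample_id in cfg.sample_ids:
            f = sample_files[sample_id]
            w.writerow(
                [
                    sample_id,
                    f["vcf_a"].name,
                    f["vcf_b"].name,
                    f["germline_vcf"].name,
                    f["depth_track"].name,
                ]
            )

    return SimBundle(
        root=outdir,
        reference=ref_path,
        repeats_bed=repeats_path,
        targets_bed=targets_path,
        population=pop_path,
        annotations=ann_path,
        truth_manifest=truth_path,
        sample_sheet=sheet_path,
        sample_files=sample_files,
    )


def _write_dialect_b_vcf(rows: list[dict], path: Path, contig_lengths: dict[str, int]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">',
        f'##INFO=<ID=SomaticEVS,Number=1,Type=Float,Description="Somatic empirical variant score">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2 counts">',
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2 counts">',
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2 counts">',
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2 counts">',
        '##FILTER=<ID=LowEVS,Description="Somatic score below threshold">',
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR")
    for r in rows:
        counts = {b: 0 for b in _BASES}
        counts[r["ref"]] = r["depth"] - r["alt_depth"]
        counts[r["alt"]] = r["alt_depth"]
        tumor = ":".join(
            [str(r["depth"])] + [f"{counts[b]},{counts[b]}" for b in _BASES]
        )
        ncounts = {b: 0 for b in _BASES}
        ncounts[r["ref"]] = r["normal_depth"]
        normal = ":".join(
            [str(r["normal_depth"])] + [f"{ncounts[b]},{ncounts[b]}" for b in _BASES]
        )
        lines.append(
            "\t".join(
                [
                    r["contig"],
                    str(r["pos1"]),
                    ".",
                    r["ref"],
                    r["alt"],
                    ".",
                    r["filter_status"],
                    f"SOMATIC;SomaticEVS={r['score']:g}",
                    "DP:AU:CU:GU:TU",
                    normal,
                    tumor,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_germline_vcf(
    truths: Sequence[TruthVariant], path: Path, contig_lengths: dict[str, int], sample_id: str
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}")
    for t in sorted(truths, key=lambda t: (t.contig, t.pos1)):
        lines.append(
            "\t".join(
                [t.contig, str(t.pos1), ".", t.ref, t.alt, "50", "PASS", ".", "GT", "0/1"]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_depth_track(
    path: Path,
    contig_lengths: dict[str, int],
    low_sites: dict[str, dict[int, int]],
    rng: np.random.Generator,
    mean_depth: float,
    window: int = 500,
) -> None:
    """Windowed normal depth, >= 10 everywhere except designed low-depth sites."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for contig, length in contig_lengths.items():
            overrides = low_sites.get(contig, {})
            for start in range(0, length, window):
                end = min(start + window, length)
                depth = max(10, int(rng.poisson(mean_depth)))
                cut_positions = sorted(p for p in overrides if start < p <= end)
                cursor = start
                for pos1 in cut_positions:
                    if pos1 - 1 > cursor:
                        w.writerow([contig, cursor, pos1 - 1, depth])
                    w.writerow([contig, pos1 - 1, pos1, overrides[pos1]])
                    cursor = pos1
                if cursor < end:
                    w.writerow([contig, cursor, end, depth])


def read_truth_manifest(path: str | Path) -> list[TruthVariant]:
    truths = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            truths.append(
                TruthVariant(
                    sample_id=row["sample"],
                    contig=row["contig"],
                    pos1=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    truth_class=TruthClass(row["class"]),
                    designed_af=float(row["designed_af"]),
                )
            )
    return truths


@dataclass
class EvaluationResult:
    n_truth_consensus: int
    n_recovered: int
    n_reported: int
    recall: float | None
    precision: float | None  # None when nothing was reported
    confusion: dict[TruthClass, dict[str, int]]

    def outcome_of(self, tclass: TruthClass) -> dict[str, int]:
        return self.confusion.get(tclass, {})


def evaluate_against_truth(
    consensus_by_sample: Mapping[str, Iterable],
    truths: Sequence[TruthVariant],
    audit_reasons: Mapping[tuple[str, VariantKey], set] | None = None,
) -> EvaluationResult:
    """Precision/recall of CONSENSUS-fate truth recovery plus a per-class
    confusion table showing where each class ended up.

    ``audit_reasons`` maps (sample, variant key) to the union of filter reasons
    across callers; with it, removed records are split into
    ``filtered_expected`` / ``filtered_other`` / ``intersection_removed``.
    """
    truth_samples = {t.sample_id for t in truths}
    unknown = set(consensus_by_sample) - truth_samples
    if unknown:
        raise InputError(f"consensus contains unknown samples: {sorted(unknown)}")

    consensus_keys: dict[str, set[VariantKey]] = {}
    n_reported = 0
    for sample_id, variants in consensus_by_sample.items():
        keys = set()
        for v in variants:
            keys.add(v if isinstance(v, tuple) else v.key)
        consensus_keys[sample_id] = keys
        n_reported += len(keys)

    confusion: dict[TruthClass, dict[str, int]] = {}
    n_truth_consensus = n_recovered = 0
    truth_keys_by_sample: dict[str, set[VariantKey]] = {}
    for t in truths:
        truth_keys_by_sample.setdefault(t.sample_id, set()).add(t.key)
        in_consensus = t.key in consensus_keys.get(t.sample_id, set())
        if t.expected_fate == "CONSENSUS":
            n_truth_consensus += 1
            if in_consensus:
                n_recovered += 1
        if in_consensus:
            outcome = "consensus"
        elif audit_reasons is not None:
            reasons = audit_reasons.get((t.sample_id, t.key), set())
            reason_values = {getattr(r, "value", r) for r in reasons}
            expected = EXPECTED_REASON.get(t.truth_class)
            if expected is not None and expected.value in reason_values:
                outcome = "filtered_expected"
            elif reason_values:
                outcome = "filtered_other"
            else:
                outcome = "intersection_removed"
        else:
            outcome = "removed"
        bucket = confusion.setdefault(t.truth_class, {})
        bucket[outcome] = bucket.get(outcome, 0) + 1

    n_true_positive = sum(
        len(keys & truth_consensus_keys(truths, sample_id))
        for sample_id, keys in consensus_keys.items()
    )
    return EvaluationResult(
        n_truth_consensus=n_truth_consensus,
        n_recovered=n_recovered,
        n_reported=n_reported,
        recall=(n_recovered / n_truth_consensus) if n_truth_consensus else None,
        precision=(n_true_positive / n_reported) if n_reported else None,
        confusion=confusion,
    )


def truth_consensus_keys(truths: Sequence[TruthVariant], sample_id: str) -> set[VariantKey]:
    return {
        t.key
        for t in truths
        if t.sample_id == sample_id and t.expected_fate == "CONSENSUS"
    }
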