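"""End-to-end orchestration: load inputs, run the cascade per caller per
sample, intersect, annotate, summarize, and write the run layout.

Every threshold actually used is materialized into ``run_manifest.yaml`` so a
run is reproducible from its outputs alone.
"""
from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import caller_io, consensus_filter, reference_context
from .caller_io import (
    AnnotationTable,
    DepthTrack,
    PopulationFrequencyTable,
    SomaticCall,
)
from .cohort_summary import CohortReport, SummaryConfig, build_cohort_report
from .consensus_filter import (
    ConsensusVariant,
    FilterConfig,
    FilterOutcome,
    attrition_summary,
    intersect_callsets,
    run_cascade,
    write_attrition_tsv,
    write_audit_tsv,
    write_consensus_tsv,
    write_consensus_vcf,
)
from .errors import ConfigError, InputError

__all__ = ["SampleInputs", "RunConfig", "SampleResult", "CohortResult", "run_pipeline"]


@dataclass
class SampleInputs:
    sample_id: str
    vcf_a: Path
    vcf_b: Path
    germline_vcf: Path | None = None
    depth_track: Path | None = None


@dataclass
class RunConfig:
    reference: Path
    sample_sheet: Path
    output_dir: Path
    repeats_bed: Path | None = None
    targets_bed: Path | None = None
    population: Path | None = None
    annotations: Path | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    summary_cfg: SummaryConfig = field(default_factory=SummaryConfig)
    af_source: str = "A"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(key: str, required: bool = False) -> Path | None:
            value = raw.get(key)
            if value is None:
                if required:
                    raise ConfigError(f"{path}: missing required key {key!r}")
                return None
            return (base / value).resolve() if not Path(value).is_absolute() else Path(value)

        cfg = cls(
            reference=resolve("reference", required=True),
            sample_sheet=resolve("sample_sheet", required=True),
            output_dir=resolve("output_dir", required=True),
            repeats_bed=resolve("repeats_bed"),
            targets_bed=resolve("targets_bed"),
            population=resolve("population"),
            annotations=resolve("annotations"),
            filter_cfg=FilterConfig(**(raw.get("filter") or {})),
            summary_cfg=SummaryConfig(**(raw.get("summary") or {})),
            af_source=str(raw.get("af_source", "A")),
        )
        return cfg

    def load_samples(self) -> list[SampleInputs]:
        base = self.sample_sheet.parent
        samples: list[SampleInputs] = []
        seen: set[str] = set()
        with open(self.sample_sheet) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                sid = row["sample"]
                if sid in seen:
                    raise InputError(f"duplicate sample id {sid!r} in sample sheet")
                seen.add(sid)

                def p(col: str) -> Path | None:
                    value = (row.get(col) or "").strip()
                    return (base / value) if value else None

                vcf_a, vcf_b = p("vcf_a"), p("vcf_b")
                if vcf_a is None or vcf_b is None:
                    raise InputError(f"sample {sid}: vcf_a and vcf_b are required")
                samples.append(
                    SampleInputs(
                        sample_id=sid,
                        vcf_a=vcf_a,
                        vcf_b=vcf_b,
                        germline_vcf=p("germline_vcf"),
                        depth_track=p("depth_track"),
                    )
                )
        return samples


@dataclass
class SampleResult:
    sample_id: str
    consensus: list[ConsensusVariant]
    audit_a: list[FilterOutcome]
    audit_b: list[FilterOutcome]
    survivors_a: list[SomaticCall]
    survivors_b: list[SomaticCall]

    @property
    def audit_reasons(self) -> dict:
        """(sample, key) -> union of reasons across callers."""
        merged: dict = {}
        for outcomes in (self.audit_a, self.audit_b):
            for o in outcomes:
                entry = merged.setdefault((self.sample_id, o.call.key), set())
                entry |= set(o.reasons)
        return merged


@dataclass
class CohortResult:
    samples: dict[str, SampleResult]
    report: CohortReport

    @property
    def consensus_by_sample(self) -> dict[str, list[ConsensusVariant]]:
        return {sid: r.consensus for sid, r in self.samples.items()}

    @property
    def audit_reasons(self) -> dict:
        merged: dict = {}
        for r in self.samples.values():
            merged.update(r.audit_reasons)
        return merged


def _write_manifest(cfg: RunConfig, path: Path) -> None:
    manifest = {
        "inputs": {
            "reference": str(cfg.reference),
            "sample_sheet": str(cfg.sample_sheet),
            "repeats_bed": str(cfg.repeats_bed) if cfg.repeats_bed else None,
            "targets_bed": str(cfg.targets_bed) if cfg.targets_bed else None,
            "population": str(cfg.population) if cfg.population else None,
            "annotations": str(cfg.annotations) if cfg.annotations else None,
        },
        "filter": dataclasses.asdict(cfg.filter_cfg),
        "summary": dataclasses.asdict(cfg.summary_cfg),
        "af_source": cfg.af_source,
    }
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> CohortResult:
    """Run the full consensus workflow over every sample in the sheet."""
    ref = reference_context.read_fasta(cfg.reference)
    runs = reference_context.scan_homopolymers(ref, cfg.filter_cfg.homopolymer_min_run)
    repeats = (
        reference_context.read_bed(cfg.repeats_bed)
        if cfg.repeats_bed
        else reference_context.IntervalSet()
    )
    freqs: PopulationFrequencyTable | None = (
        caller_io.read_population_frequencies(cfg.population) if cfg.population else None
    )
    annotations: AnnotationTable | None = (
        caller_io.read_annotation_table(cfg.annotations) if cfg.annotations else None
    )

    outdir = Path(cfg.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_manifest(cfg, outdir / "run_manifest.yaml")

    results: dict[str, SampleResult] = {}
    attrition_rows = []
    audit_rows = []
    for sample in cfg.load_samples():
        calls_a = [
            caller_io.normalize_variant(c, ref)
            for c in caller_io.read_somatic_vcf(sample.vcf_a, "A", sample.sample_id)
        ]
        calls_b = [
            caller_io.normalize_variant(c, ref)
            for c in caller_io.read_somatic_vcf(sample.vcf_b, "B", sample.sample_id)
        ]
        germline_keys = (
            caller_io.read_germline_keys(sample.germline_vcf, ref)
            if sample.germline_vcf
            else set()
        )
        track: DepthTrack | None = (
            caller_io.read_depth_track(sample.depth_track) if sample.depth_track else None
        )
        survivors = {}
        audits = {}
        for label, calls in (("A", calls_a), ("B", calls_b)):
            survivors[label], audits[label] = run_cascade(
                calls,
                runs=runs,
                repeats=repeats,
                depth_track=track,
                freqs=freqs,
                germline_keys=germline_keys,
                cfg=cfg.filter_cfg,
            )
            attrition_rows.append(
                (sample.sample_id, label, attrition_summary(audits[label]))
            )
            audit_rows.append((label, audits[label]))
        consensus = intersect_callsets(
            survivors["A"], survivors["B"], af_source=cfg.af_source
        )
        if annotations is not None:
            consensus = [
                dataclasses.replace(v, annotation=annotations.get(v.key))
                for v in consensus
            ]
        results[sample.sample_id] = SampleResult(
            sample_id=sample.sample_id,
            consensus=consensus,
            audit_a=audits["A"],
            audit_b=audits["B"],
            survivors_a=survivors["A"],
            survivors_b=survivors["B"],
        )
        if write_outputs:
            write_consensus_tsv(consensus, outdir / f"{sample.sample_id}.consensus.tsv")
            write_consensus_vcf(
                consensus, outdir / f"{sample.sample_id}.consensus.vcf", ref.lengths
            )

    report = build_cohort_report(
        {sid: r.consensus for sid, r in results.items()},
        annotations=annotations,
        cfg=cfg.summary_cfg,
    )
    if write_outputs:
        write_audit_tsv(audit_rows, outdir / "audit.tsv")
        write_attrition_tsv(attrition_rows, outdir / "attrition.tsv")
        report.write(outdir)
    return CohortResult(samples=results, report=report)
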