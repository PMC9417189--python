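"""Cohort-level summaries over per-sample consensus variant sets.

Covers subclonality (AF strictly below the threshold), transition/transversion
ratio, consequence-category tallies with an exonic roll-up, CADD Phred tiers
(exclusive and cumulative), and position- and gene-level recurrence across
samples.  The functions accept any records exposing the
:class:`SummaryVariant` attributes, so the stage also runs directly on a
standalone pre-annotated variant table.
"""
from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller_io import (
    AnnotationTable,
    VariantKey,
    _parse_fraction,
    _resolve_columns,
    normalize_consequence,
)
from .consensus_filter import ConsensusVariant
from .errors import InputError

__all__ = [
    "SummaryConfig",
    "SummaryVariant",
    "CaddTiers",
    "RecurrentPosition",
    "GeneRecurrence",
    "CohortReport",
    "classify_subclonal",
    "titv_ratio",
    "tally_consequences",
    "cadd_tiers",
    "recurrent_positions",
    "recurrent_genes",
    "build_cohort_report",
    "load_variant_table",
    "consequence_category",
    "CONSEQUENCE_CATEGORIES",
    "EXONIC_CATEGORIES",
]


@dataclass(frozen=True)
class SummaryConfig:
    subclonal_af_threshold: float = 0.20
    cadd_high_tier: float = 30.0
    cadd_mid_tier: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.subclonal_af_threshold < 1.0:
            raise InputError("subclonal_af_threshold must be in (0,1)")
        if self.cadd_mid_tier >= self.cadd_high_tier:
            raise InputError("cadd_mid_tier must be below cadd_high_tier")


@dataclass(frozen=True)
class SummaryVariant:
    """Minimal annotated variant view the summary stage operates on."""

    sample_id: str
    contig: str
    pos1: int
    ref_allele: str
    alt_allele: str
    allele_fraction: float | None = None
    gene: str | None = None
    consequence: str | None = None
    cadd_phred: float | None = None
    population_freq: float | None = None

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @classmethod
    def from_consensus(cls, v: ConsensusVariant) -> "SummaryVariant":
        ann = v.annotation
        return cls(
            sample_id=v.sample_id,
            contig=v.contig,
            pos1=v.pos1,
            ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            allele_fraction=v.allele_fraction,
            gene=ann.gene_symbol if ann else None,
            consequence=ann.consequence if ann else None,
            cadd_phred=ann.cadd_phred if ann else None,
            population_freq=ann.population_freq if ann else None,
        )


def _as_summary(v) -> SummaryVariant:
    return SummaryVariant.from_consensus(v) if isinstance(v, ConsensusVariant) else v


def classify_subclonal(af: float, cfg: SummaryConfig = SummaryConfig()) -> bool:
    """True iff the allele fraction is strictly below the subclonal threshold."""
    if not 0.0 <= af <= 1.0:
        raise InputError(f"allele fraction {af} outside [0,1]")
    return af < cfg.subclonal_af_threshold


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(ref: str, alt: str) -> bool:
    return ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)


def titv_ratio(variants: Iterable) -> float | None:
    """Transition/transversion ratio over SNVs; None when no transversions."""
    n_ts = n_tv = 0
    for v in map(_as_summary, variants):
        if not v.is_snv:
            continue
        if is_transition(v.ref_allele, v.alt_allele):
            n_ts += 1
        else:
            n_tv += 1
    if n_tv == 0:
        return None
    return n_ts / n_tv


# Fixed mapping from SO-style consequence strings to report categories.
CONSEQUENCE_CATEGORIES: dict[str, str] = {
    "missense_variant": "amino_acid_changing",
    "stop_gained": "amino_acid_changing",
    "stop_lost": "amino_acid_changing",
    "start_lost": "amino_acid_changing",
    "protein_altering_variant": "amino_acid_changing",
    "frameshift_variant": "amino_acid_changing",
    "inframe_insertion": "amino_acid_changing",
    "inframe_deletion": "amino_acid_changing",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "start_retained_variant": "synonymous",
    "3_prime_utr_variant": "utr3",
    "5_prime_utr_variant": "utr5",
    "non_coding_transcript_exon_variant": "noncoding_exon",
    "intron_variant": "intron",
    "splice_region_variant": "splice_region",
    "splice_acceptor_variant": "splice_region",
    "splice_donor_variant": "splice_region",
    "upstream_gene_variant": "upstream_downstream",
    "downstream_gene_variant": "upstream_downstream",
    "intergenic_variant": "intergenic",
}

CATEGORY_ORDER = [
    "amino_acid_changing",
    "synonymous",
    "utr3",
    "utr5",
    "noncoding_exon",
    "intron",
    "splice_region",
    "upstream_downstream",
    "intergenic",
    "other",
]

EXONIC_CATEGORIES = ("amino_acid_changing", "synonymous", "utr3", "utr5", "noncoding_exon")


def consequence_category(consequence: str | None) -> str:
    if consequence is None:
        return "other"
    return CONSEQUENCE_CATEGORIES.get(normalize_consequence(consequence), "other")


def tally_consequences(variants: Iterable) -> dict[str, int]:
    """Count variants per consequence category (every category present, incl. zero)."""
    tally = {c: 0 for c in CATEGORY_ORDER}
    for v in map(_as_summary, variants):
        tally[consequence_category(v.consequence)] += 1
    return tally


def exonic_count(tally: Mapping[str, int]) -> int:
    return sum(tally[c] for c in EXONIC_CATEGORIES)


@dataclass(frozen=True)
class CaddTiers:
    n_above_high: int  # cadd > high tier (default > 30)
    n_mid_exclusive: int  # mid < cadd <= high (default 20 < cadd <= 30)
    n_above_mid_cumulative: int  # cadd > mid tier
    n_unknown: int


def cadd_tiers(variants: Iterable, cfg: SummaryConfig = SummaryConfig()) -> CaddTiers:
    high = mid = unknown = 0
    for v in map(_as_summary, variants):
        score = v.cadd_phred
        if score is None:
            unknown += 1
        elif score > cfg.cadd_high_tier:
            high += 1
        elif score > cfg.cadd_mid_tier:
            mid += 1
    return CaddTiers(high, mid, high + mid, unknown)


@dataclass(frozen=True)
class RecurrentPosition:
    key: VariantKey
    samples: tuple[str, ...]
    allele_fractions: tuple[float | None, ...]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def recurrent_positions(cohort: Mapping[str, Sequence]) -> list[RecurrentPosition]:
    """Variant keys present in >= 2 samples, by descending sample count then position."""
    hits: dict[VariantKey, list[tuple[str, float | None]]] = defaultdict(list)
    for sample_id in cohort:
        for v in map(_as_summary, cohort[sample_id]):
            hits[v.key].append((sample_id, v.allele_fraction))
    out = []
    for key, entries in hits.items():
        samples = sorted({s for s, _ in entries})
        if len(samples) < 2:
            continue
        by_sample = dict(entries)
        out.append(
            RecurrentPosition(
                key,
                tuple(samples),
                tuple(by_sample[s] for s in samples),
            )
        )
    out.sort(key=lambda r: (-r.n_samples, r.key))
    return out


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    entries: tuple[tuple[str, VariantKey, str | None, float | None], ...]  # (sample, key, consequence, cadd)
    position_level_only: bool  # qualifies only via one identical shared variant

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, *_ in self.entries}))


def recurrent_genes(cohort: Mapping[str, Sequence]) -> list[GeneRecurrence]:
    """Genes carrying consensus variants in >= 2 distinct samples.

    Genes that qualify only because the identical variant is shared are
    flagged ``position_level_only`` (they belong in the recurrent-position
    listing, not the gene-level one).
    """
    by_gene: dict[str, list[tuple[str, VariantKey, str | None, float | None]]] = defaultdict(list)
    for sample_id in cohort:
        for v in map(_as_summary, cohort[sample_id]):
            if v.gene:
                by_gene[v.gene].append((sample_id, v.key, v.consequence, v.cadd_phred))
    out = []
    for gene in sorted(by_gene):
        entries = sorted(by_gene[gene], key=lambda e: (e[1], e[0]))
        samples = {s for s, *_ in entries}
        if len(samples) < 2:
            continue
        distinct_keys = {k for _, k, *_ in entries}
        out.append(
            GeneRecurrence(gene, tuple(entries), position_level_only=len(distinct_keys) == 1)
        )
    return out


@dataclass
class CohortReport:
    n_samples: int
    per_sample_counts: dict[str, int]
    total_variants: int
    mean_per_sample: float
    count_range: tuple[int, int]
    consequence_tally: dict[str, int]
    exonic_total: int
    titv: float | None
    n_subclonal: int
    n_clonal: int
    n_af_known: int
    subclonal_percent: float | None
    cadd: CaddTiers
    recurrent_positions: list[RecurrentPosition]
    recurrent_genes: list[GeneRecurrence]

    def to_text(self) -> str:
        lines = [
            "Cohort summary",
            "==============",
            f"samples: {self.n_samples}",
            f"total consensus variants: {self.total_variants}",
            f"mean per sample: {self.mean_per_sample:.1f}",
            f"range per sample: {self.count_range[0]}-{self.count_range[1]}",
            "",
            "Consequence tally:",
        ]
        for cat in CATEGORY_ORDER:
            lines.append(f"  {cat}: {self.consequence_tally[cat]}")
        lines.append(f"  exonic (roll-up): {self.exonic_total}")
        lines.append("")
        titv = "undefined (no transversions)" if self.titv is None else f"{self.titv:.2f}"
        lines.append(f"Ti/Tv ratio: {titv}")
        sub = (
            "undefined (no AF data)"
            if self.subclonal_percent is None
            else f"{self.n_subclonal} ({self.subclonal_percent:.2f}% of {self.n_af_known} with AF)"
        )
        lines.append(f"Subclonal variants (AF < threshold): {sub}")
        lines.append(
            f"CADD tiers: >high {self.cadd.n_above_high}, mid-band {self.cadd.n_mid_exclusive}, "
            f"cumulative {self.cadd.n_above_mid_cumulative}, unknown {self.cadd.n_unknown}"
        )
        lines.append("")
        lines.append(f"Recurrent positions (>=2 samples): {len(self.recurrent_positions)}")
        for r in self.recurrent_positions:
            key = f"{r.key[0]}:{r.key[1]} {r.key[2]}/{r.key[3]}"
            lines.append(f"  {key} in {', '.join(r.samples)}")
        gene_level = [g for g in self.recurrent_genes if not g.position_level_only]
        lines.append(f"Recurrent genes (>=2 samples, gene level): {len(gene_level)}")
        for g in gene_level:
            lines.append(f"  {g.gene} in {', '.join(g.samples)}")
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "cohort_summary.txt").write_text(self.to_text())
        with open(outdir / "per_sample_counts.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample", "n_variants"])
            for sample in sorted(self.per_sample_counts):
                w.writerow([sample, self.per_sample_counts[sample]])
        with open(outdir / "consequence_tally.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["category", "count"])
            for cat in CATEGORY_ORDER:
                w.writerow([cat, self.consequence_tally[cat]])
            w.writerow(["exonic_rollup", self.exonic_total])
        with open(outdir / "recurrent_positions.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["contig", "pos", "ref", "alt", "n_samples", "samples", "allele_fractions"])
            for r in self.recurrent_positions:
                w.writerow(
                    list(r.key)
                    + [
                        r.n_samples,
                        ",".join(r.samples),
                        ",".join("" if a is None else f"{a:.4f}" for a in r.allele_fractions),
                    ]
                )
        with open(outdir / "recurrent_genes.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "n_samples", "samples", "position_level_only", "variants"])
            for g in self.recurrent_genes:
                w.writerow(
                    [
                        g.gene,
                        len(g.samples),
                        ",".join(g.samples),
                        int(g.position_level_only),
                        ";".join(f"{s}:{k[0]}:{k[1]}:{k[2]}>{k[3]}" for s, k, _c, _d in g.entries),
                    ]
                )


def build_cohort_report(
    cohort: Mapping[str, Sequence],
    annotations: AnnotationTable | None = None,
    cfg: SummaryConfig = SummaryConfig(),
) -> CohortReport:
    """Assemble every summary statistic over a sample -> variants mapping."""
    enriched: dict[str, list[SummaryVariant]] = {}
    for sample_id in cohort:
        rows = []
        for v in map(_as_summary, cohort[sample_id]):
            if annotations is not None and (v.consequence is None and v.gene is None):
                ann = annotations.get(v.key)
                if ann is not None:
                    v = SummaryVariant(
                        sample_id=v.sample_id,
                        contig=v.contig,
                        pos1=v.pos1,
                        ref_allele=v.ref_allele,
                        alt_allele=v.alt_allele,
                        allele_fraction=v.allele_fraction,
                        gene=ann.gene_symbol,
                        consequence=ann.consequence,
                        cadd_phred=ann.cadd_phred,
                        population_freq=ann.population_freq,
                    )
            rows.append(v)
        enriched[sample_id] = rows

    all_variants = [v for rows in enriched.values() for v in rows]
    per_sample = {s: len(rows) for s, rows in enriched.items()}
    total = len(all_variants)
    counts = list(per_sample.values()) or [0]
    n_sub = n_known = 0
    for v in all_variants:
        if v.allele_fraction is not None:
            n_known += 1
            if classify_subclonal(v.allele_fraction, cfg):
                n_sub += 1
    return CohortReport(
        n_samples=len(enriched),
        per_sample_counts=per_sample,
        total_variants=total,
        mean_per_sample=total / len(enriched) if enriched else 0.0,
        count_range=(min(counts), max(counts)),
        consequence_tally=tally_consequences(all_variants),
        exonic_total=exonic_count(tally_consequences(all_variants)),
        titv=titv_ratio(all_variants),
        n_subclonal=n_sub,
        n_clonal=n_known - n_sub,
        n_af_known=n_known,
        subclonal_percent=(100.0 * n_sub / n_known) if n_known else None,
        cadd=cadd_tiers(all_variants, cfg),
        recurrent_positions=recurrent_positions(enriched),
        recurrent_genes=recurrent_genes(enriched),
    )


_TABLE_COLUMNS = {
    "sample": ("sample", "sample_id", "pitnet_sample", "patient"),
    "contig": ("contig", "chrom", "chr", "chromosome"),
    "pos": ("pos", "pos1", "position"),
    "ref": ("ref", "ref_allele", "reference"),
    "alt": ("alt", "alt_allele", "alternative"),
}
_OPTIONAL_COLUMNS = {
    "af": ("allele_fraction", "af", "alt_allele_fraction", "vaf"),
    "gene": ("gene", "gene_symbol"),
    "consequence": ("consequence", "consequences", "effect"),
    "cadd": ("cadd_phred", "cadd", "cadd_score"),
    "pop_freq": ("pop_freq", "population_freq", "gnomad_freq", "maf"),
}


def load_variant_table(path: str | Path) -> dict[str, list[SummaryVariant]]:
    """Load a standalone pre-annotated variant table (TSV or XLSX).

    Column names are resolved against candidate lists; an unresolvable
    mandatory column raises an input error naming the candidates.  Allele
    fractions accept both fractions (0.417) and percent strings ("41.7%").
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(list(df.columns), _TABLE_COLUMNS)
    lower = {c.lower().strip(): c for c in df.columns}
    opt = {
        f: next((lower[c] for c in cands if c in lower), None)
        for f, cands in _OPTIONAL_COLUMNS.items()
    }

    def clean(value, parse=str):
        if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
            return None
        text = str(value).strip()
        if text in ("", ".", "NA", "nan"):
            return None
        return parse(text)

    cohort: dict[str, list[SummaryVariant]] = defaultdict(list)
    for _, row in df.iterrows():
        sample = clean(row[cols["sample"]])
        if sample is None:
            continue
        af = clean(row[opt["af"]], _parse_fraction) if opt["af"] else None
        consequence = clean(row[opt["consequence"]]) if opt["consequence"] else None
        cohort[sample].append(
            SummaryVariant(
                sample_id=sample,
                contig=str(clean(row[cols["contig"]])).replace(" ", ""),
                pos1=int(str(clean(row[cols["pos"]])).replace(" ", "")),
                ref_allele=str(clean(row[cols["ref"]])),
                alt_allele=str(clean(row[cols["alt"]])),
                allele_fraction=af,
                gene=clean(row[opt["gene"]]) if opt["gene"] else None,
                consequence=normalize_consequence(consequence) if consequence else None,
                cadd_phred=clean(row[opt["cadd"]], float) if opt["cadd"] else None,
                population_freq=clean(row[opt["pop_freq"]], _parse_fraction)
                if opt["pop_freq"]
                else None,
            )
        )
    return dict(cohort)
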