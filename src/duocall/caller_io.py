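"""Readers for the two somatic caller dialects, germline VCFs, depth tracks,
population-frequency tables and variant annotation tables.

Dialect A is an allele-depth-reporting somatic VCF: record-level QUAL plus
per-sample DP/AD, with the tumor in a sample column named after the sample.
Dialect B is a tiered-count somatic VCF: a site-level somatic quality score in
INFO (key ``SomaticEVS``), per-allele tier-1/tier-2 base counts (AU/CU/GU/TU
for SNVs, TAR/TIR for indels) and a sample column named ``TUMOR``.

Both are normalized into :class:`SomaticCall` records carrying one unified
``qual_score`` so a single threshold can be applied across all result files.
"""
from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .errors import FormatError, InputError, ReferenceMismatchError
from .reference_context import ReferenceSet

log = logging.getLogger(__name__)

DIALECT_B_SCORE_KEY = "SomaticEVS"  # redirectable: the unified-score INFO key for dialect B
_BASE_COUNT_KEYS = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}
_DNA = re.compile(r"^[ACGT]+$")

VariantKey = tuple[str, int, str, str]

__all__ = [
    "SomaticCall",
    "PopulationFrequencyTable",
    "AnnotationRecord",
    "AnnotationTable",
    "DepthTrack",
    "VariantKey",
    "read_somatic_vcf",
    "write_dialect_a_vcf",
    "read_germline_keys",
    "normalize_variant",
    "normalize_consequence",
    "read_population_frequencies",
    "read_annotation_table",
    "read_depth_track",
    "depth_at",
    "CONSEQUENCE_VOCABULARY",
]


@dataclass(frozen=True)
class SomaticCall:
    """One caller-reported tumor variant, normalized across dialects."""

    sample_id: str
    caller_id: str  # "A" or "B"
    contig: str
    pos1: int
    ref_allele: str
    alt_allele: str
    filter_status: str
    qual_score: float
    tumor_alt_depth: int
    tumor_total_depth: int
    normal_depth: int | None = None
    dbsnp_id: str | None = None

    def __post_init__(self) -> None:
        if self.tumor_alt_depth > self.tumor_total_depth:
            raise InputError(
                f"alt depth {self.tumor_alt_depth} > total {self.tumor_total_depth} "
                f"at {self.contig}:{self.pos1}"
            )
        if self.ref_allele == self.alt_allele:
            raise InputError(f"REF == ALT at {self.contig}:{self.pos1}")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref_allele, self.alt_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def allele_fraction(self) -> float | None:
        if self.tumor_total_depth == 0:
            return None
        return self.tumor_alt_depth / self.tumor_total_depth


def _tumor_sample_name(header_samples: list[str], dialect: str, sample_id: str) -> str:
    wanted = sample_id if dialect == "A" else "TUMOR"
    if wanted in header_samples:
        return wanted
    if dialect == "A" and "TUMOR" in header_samples:
        return "TUMOR"
    raise InputError(
        f"tumor sample column {wanted!r} not found (samples: {header_samples})"
    )


def _normal_sample_name(header_samples: list[str], tumor: str) -> str | None:
    others = [s for s in header_samples if s != tumor]
    if "NORMAL" in others:
        return "NORMAL"
    return others[0] if others else None


def read_somatic_vcf(
    path: str | Path,
    dialect: str,
    sample_id: str,
    stats: dict | None = None,
) -> list[SomaticCall]:
    """Read one caller's somatic VCF into SomaticCall records.

    Multi-allelic records are split into one call per ALT allele; symbolic and
    breakend ALTs are skipped with a logged count (also reported via ``stats``
    under ``n_skipped`` / ``n_alt_alleles`` when a dict is supplied).
    """
    if dialect not in ("A", "B"):
        raise InputError(f"unknown dialect {dialect!r}")
    calls: list[SomaticCall] = []
    n_skipped = 0
    n_alt = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        tumor = _tumor_sample_name(samples, dialect, sample_id)
        normal = _normal_sample_name(samples, tumor)
        for rec in vcf:
            for alt in rec.alts or ():
                n_alt += 1
                if not (_DNA.match(alt or "") and _DNA.match(rec.ref or "")):
                    n_skipped += 1
                    continue
                calls.append(
                    _record_to_call(rec, alt, dialect, sample_id, tumor, normal)
                )
    if n_skipped:
        log.info("%s: skipped %d symbolic/non-ACGT ALT alleles", path, n_skipped)
    if stats is not None:
        stats["n_skipped"] = n_skipped
        stats["n_alt_alleles"] = n_alt
    return calls


def _record_to_call(rec, alt, dialect, sample_id, tumor, normal) -> SomaticCall:
    filter_status = ";".join(rec.filter.keys()) if list(rec.filter) else "PASS"
    tdata = rec.samples[tumor]
    normal_depth = None
    if normal is not None:
        ndp = rec.samples[normal].get("DP")
        if ndp is not None:
            normal_depth = int(ndp)
    if dialect == "A":
        qual = float(rec.qual) if rec.qual is not None else 0.0
        ad = tdata.get("AD")
        if ad is None:
            raise FormatError(f"dialect A record without AD at {rec.contig}:{rec.pos}")
        alt_index = list(rec.alts).index(alt) + 1
        alt_depth = int(ad[alt_index])
        total_depth = int(sum(int(x) for x in ad if x is not None))
    else:
        score = rec.info.get(DIALECT_B_SCORE_KEY)
        qual = float(score) if score is not None else 0.0
        if len(rec.ref) == 1 and len(alt) == 1:
            counts = {}
            for base, key in _BASE_COUNT_KEYS.items():
                val = tdata.get(key)
                counts[base] = int(val[0]) if val is not None else 0
            alt_depth = counts[alt]
            total_depth = sum(counts.values())
        else:  # indel: tier-1 TAR (ref-supporting) + TIR (indel-supporting)
            tar = tdata.get("TAR")
            tir = tdata.get("TIR")
            alt_depth = int(tir[0]) if tir is not None else 0
            total_depth = alt_depth + (int(tar[0]) if tar is not None else 0)
    return SomaticCall(
        sample_id=sample_id,
        caller_id=dialect,
        contig=rec.contig,
        pos1=rec.pos,
        ref_allele=rec.ref,
        alt_allele=alt,
        filter_status=filter_status,
        qual_score=qual,
        tumor_alt_depth=alt_depth,
        tumor_total_depth=max(total_depth, alt_depth),
        normal_depth=normal_depth,
        dbsnp_id=rec.id if rec.id not in (None, ".") else None,
    )


def write_dialect_a_vcf(
    calls: Iterable[SomaticCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    sample_id: str,
) -> None:
    """Write calls as a dialect-A VCF (QUAL + NORMAL/tumor DP:AD columns)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FILTER=<ID=LowSupport,Description="Insufficient somatic evidence">',
    ]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\t" + sample_id
    )
    for call in sorted(calls, key=lambda c: (c.contig, c.pos1, c.ref_allele, c.alt_allele)):
        ndp = call.normal_depth if call.normal_depth is not None else "."
        ref_depth = call.tumor_total_depth - call.tumor_alt_depth
        lines.append(
            "\t".join(
                [
                    call.contig,
                    str(call.pos1),
                    call.dbsnp_id or ".",
                    call.ref_allele,
                    call.alt_allele,
                    f"{call.qual_score:g}",
                    call.filter_status,
                    ".",
                    "GT:DP:AD",
                    f"0/0:{ndp}:.",
                    f"0/1:{call.tumor_total_depth}:{ref_depth},{call.tumor_alt_depth}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_germline_keys(
    path: str | Path, ref: ReferenceSet | None = None
) -> set[VariantKey]:
    """Read a germline VCF into a set of normalized variant keys."""
    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if not (_DNA.match(alt or "") and _DNA.match(rec.ref or "")):
                    continue
                contig, pos1, r, a = rec.contig, rec.pos, rec.ref, alt
                if ref is not None:
                    contig, pos1, r, a = _normalize_key(contig, pos1, r, a, ref)
                keys.add((contig, pos1, r, a))
    return keys


def _normalize_key(
    contig: str, pos1: int, ref_allele: str, alt_allele: str, ref: ReferenceSet
) -> VariantKey:
    """Trim shared bases and left-align indels against the reference."""
    r, a = ref_allele, alt_allele
    # trim shared suffix, left-aligning through repeats by pulling in reference bases
    while True:
        while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
        if r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
            if pos1 <= 1:
                break
            prev = ref.base_at(contig, pos1 - 1)
            r, a = prev + r[:-1], prev + a[:-1]
            pos1 -= 1
        else:
            break
    # trim shared prefix (keep one anchor base for indels)
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos1 += 1
    expected = ref.slice(contig, pos1, pos1 + len(r) - 1)
    if expected != r:
        raise ReferenceMismatchError(
            f"REF {r!r} does not match reference {expected!r} at {contig}:{pos1}"
        )
    return contig, pos1, r, a


def normalize_variant(call: SomaticCall, ref: ReferenceSet) -> SomaticCall:
    """Return the call with trimmed, left-aligned, reference-checked alleles."""
    contig, pos1, r, a = _normalize_key(
        call.contig, call.pos1, call.ref_allele, call.alt_allele, ref
    )
    if (contig, pos1, r, a) == call.key:
        return call
    return replace(call, contig=contig, pos1=pos1, ref_allele=r, alt_allele=a)


class PopulationFrequencyTable:
    """Keyed lookup of population minor-allele frequencies."""

    def __init__(self, records: dict[VariantKey, float]) -> None:
        for key, maf in records.items():
            if not 0.0 <= maf <= 1.0:
                raise FormatError(f"MAF {maf} outside [0,1] for {key}")
        self._records = dict(records)
        self._by_position: dict[tuple[str, int], float] = {}
        for (contig, pos1, _r, _a), maf in records.items():
            prev = self._by_position.get((contig, pos1))
            self._by_position[(contig, pos1)] = max(maf, prev) if prev is not None else maf

    def get(self, key: VariantKey) -> float | None:
        return self._records.get(key)

    def max_at_position(self, contig: str, pos1: int) -> float | None:
        """Highest MAF of any allele at the position (position-only matching mode)."""
        return self._by_position.get((contig, pos1))

    def __len__(self) -> int:
        return len(self._records)


def read_population_frequencies(path: str | Path) -> PopulationFrequencyTable:
    """Read a population frequency source: VCF with AF INFO, or 5-column TSV."""
    path = Path(path)
    records: dict[VariantKey, float] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                afs = rec.info.get("AF")
                if afs is None:
                    continue
                if not isinstance(afs, tuple):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    records[(rec.contig, rec.pos, rec.ref, alt)] = float(af)
    else:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None if first.split("\t")[0] not in ("contig", "chrom", "chr") else 0,
            names=["contig", "pos1", "ref", "alt", "maf"],
            dtype={"contig": str},
        )
        for row in df.itertuples(index=False):
            records[(str(row.contig), int(row.pos1), str(row.ref), str(row.alt))] = float(
                row.maf
            )
    return PopulationFrequencyTable(records)


# Controlled consequence vocabulary (Sequence Ontology style).  Strings outside
# this set are preserved verbatim but classified "other" downstream.
CONSEQUENCE_VOCABULARY = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "synonymous_variant",
        "stop_retained_variant",
        "start_retained_variant",
        "3_prime_utr_variant",
        "5_prime_utr_variant",
        "non_coding_transcript_exon_variant",
        "intron_variant",
        "splice_region_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intergenic_variant",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
    }
)

_ID_TOKEN = re.compile(r"^(rs\d+|COSV\w+|COSM\d+)$", re.IGNORECASE)


def normalize_consequence(raw: str) -> str:
    """Normalize a free-form consequence label to SO style.

    Handles human-entered forms like ``"Missense variant, COSV57111433"``:
    trailing comma-separated database identifiers are dropped, spaces and
    hyphens become underscores, apostrophe forms like ``3' UTR`` are expanded,
    and multi-consequence ``&`` chains keep their first (most severe) term.
    """
    token = raw.strip()
    parts = [p.strip() for p in token.split(",") if p.strip()]
    parts = [p for p in parts if not _ID_TOKEN.match(p)]
    token = parts[0] if parts else ""
    token = token.split("&")[0].strip()
    token = token.replace("3'", "3 prime").replace("5'", "5 prime")
    token = re.sub(r"[\s\-]+", "_", token).lower()
    token = re.sub(r"_+", "_", token).strip("_")
    if token and not token.endswith("_variant") and f"{token}_variant" in CONSEQUENCE_VOCABULARY:
        token = f"{token}_variant"
    return token


@dataclass(frozen=True)
class AnnotationRecord:
    contig: str
    pos1: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str | None
    consequence: str
    cadd_phred: float | None
    population_freq: float | None

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos1, self.ref_allele, self.alt_allele)

    @property
    def in_vocabulary(self) -> bool:
        return self.consequence in CONSEQUENCE_VOCABULARY


class AnnotationTable:
    def __init__(self, records: dict[VariantKey, AnnotationRecord]) -> None:
        self._records = dict(records)

    def get(self, key: VariantKey) -> AnnotationRecord | None:
        return self._records.get(key)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())


_ANNOTATION_COLUMNS = {
    "contig": ("contig", "chrom", "chr", "chromosome"),
    "pos": ("pos", "pos1", "position"),
    "ref": ("ref", "ref_allele", "reference"),
    "alt": ("alt", "alt_allele", "alternative"),
    "gene": ("gene", "gene_symbol"),
    "consequence": ("consequence", "consequences", "effect"),
    "cadd_phred": ("cadd_phred", "cadd", "cadd_score"),
    "pop_freq": ("pop_freq", "population_freq", "gnomad_freq", "maf"),
}


def _resolve_columns(columns: list[str], mandatory: dict[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved = {}
    missing = []
    for field, candidates in mandatory.items():
        for cand in candidates:
            if cand in lower:
                resolved[field] = lower[cand]
                break
        else:
            missing.append(f"{field} (one of {', '.join(candidates)})")
    if missing:
        raise InputError("missing mandatory column(s): " + "; ".join(missing))
    return resolved


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a per-variant annotation TSV (gene, consequence, CADD, pop freq)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(list(df.columns), _ANNOTATION_COLUMNS)
    records: dict[VariantKey, AnnotationRecord] = {}
    for _, row in df.iterrows():
        vals = {f: row[cols[f]] for f in cols}
        key = (
            str(vals["contig"]),
            int(vals["pos"]),
            str(vals["ref"]),
            str(vals["alt"]),
        )
        gene = vals["gene"]
        gene = None if pd.isna(gene) or gene in ("", ".") else str(gene)
        cadd = vals["cadd_phred"]
        cadd = None if pd.isna(cadd) or cadd == "" else float(cadd)
        pf = vals["pop_freq"]
        pf = None if pd.isna(pf) or pf == "" else _parse_fraction(str(pf))
        records[key] = AnnotationRecord(
            *key,
            gene_symbol=gene,
            consequence=normalize_consequence(str(vals["consequence"])),
            cadd_phred=cadd,
            population_freq=pf,
        )
    return AnnotationTable(records)


def _parse_fraction(text: str) -> float:
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


class DepthTrack:
    """Per-contig map of 0-based half-open intervals to integer depth."""

    def __init__(self, rows: Iterable[tuple[str, int, int, int]]) -> None:
        by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for contig, start, end, depth in rows:
            if depth < 0:
                raise FormatError(f"negative depth {depth} at {contig}:{start}-{end}")
            if start >= end:
                raise FormatError(f"empty depth interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((start, end, depth))
        self._starts: dict[str, list[int]] = {}
        self._rows: dict[str, list[tuple[int, int, int]]] = {}
        for contig, rows_ in by_contig.items():
            rows_.sort()
            for (s1, e1, _), (s2, _e2, _d) in zip(rows_, rows_[1:]):
                if s2 < e1:
                    raise FormatError(f"overlapping depth intervals on {contig}")
            self._rows[contig] = rows_
            self._starts[contig] = [r[0] for r in rows_]

    def depth_at(self, contig: str, pos1: int) -> int:
        """Depth of the interval covering the position; 0 when uncovered."""
        starts = self._starts.get(contig)
        if not starts:
            return 0
        pos0 = pos1 - 1
        i = bisect.bisect_right(starts, pos0) - 1
        if i >= 0:
            s, e, d = self._rows[contig][i]
            if s <= pos0 < e:
                return d
        return 0


def depth_at(track: DepthTrack, contig: str, pos1: int) -> int:
    return track.depth_at(contig, pos1)


def read_depth_track(path: str | Path) -> DepthTrack:
    """Read a bedgraph-style TSV (contig, start0, end0, depth)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["contig", "start", "end", "depth"],
            dtype={"contig": str},
        )
    except pd.errors.EmptyDataError:
        return DepthTrack([])
    return DepthTrack(
        (str(r.contig), int(r.start), int(r.end), int(r.depth))
        for r in df.itertuples(index=False)
    )
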