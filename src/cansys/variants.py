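"""Variant ingestion, normalization, filtering, and annotation.

Variants are read from standard VCF (plain or bgzipped, GRCh38, 1-based),
split per alternate allele, annotated from tab-separated lookup tables
(CADD Phred, gnomAD allele frequency, gene assignment), and filtered
under per-origin policies before gene-level scoring.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger(__name__)

SOMATIC = "somatic"
GERMLINE = "germline"
_ORIGINS = (SOMATIC, GERMLINE)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized variant call for a single alternate allele.

    ``vaf`` is recomputed as ``allele_depth / total_depth``; a caller-supplied
    AF FORMAT field is deliberately ignored so the semantics are uniform
    across variant callers.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # "SNV" | "INDEL"
    origin: str  # "somatic" | "germline"
    allele_depth: Optional[int] = None
    total_depth: Optional[int] = None
    vaf: Optional[float] = None
    cadd_phred: Optional[float] = None
    gnomad_af: Optional[float] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("alt must be a single allele; split multi-allelics first")
        if self.origin not in _ORIGINS:
            raise ValueError(f"origin must be one of {_ORIGINS}, got {self.origin!r}")
        if self.cadd_phred is not None and not (0.0 <= self.cadd_phred <= 99.0):
            raise ValueError(f"CADD Phred out of [0, 99]: {self.cadd_phred}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized (chrom, pos, ref, alt) lookup key."""
        return normalize_allele(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterPolicy:
    """Retention thresholds for one variant origin.

    Retained iff allele_depth >= min_ad AND vaf > min_vaf AND
    (max_gnomad_af is None OR gnomad_af <= max_gnomad_af, missing AF passes)
    AND cadd_phred >= min_cadd (missing CADD fails when min_cadd > 0).
    """

    origin: str
    min_ad: int = 5
    min_vaf: float = 0.05
    max_gnomad_af: Optional[float] = None
    min_cadd: float = 0.0

    def __post_init__(self) -> None:
        if self.min_ad < 0 or self.min_vaf < 0 or self.min_cadd < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.max_gnomad_af is not None and self.max_gnomad_af < 0:
            raise ValueError("max_gnomad_af must be non-negative")
        if self.origin not in _ORIGINS:
            raise ValueError(f"origin must be one of {_ORIGINS}")

    @classmethod
    def somatic_default(cls, min_cadd: float = 15.0) -> "FilterPolicy":
        return cls(origin=SOMATIC, min_ad=5, min_vaf=0.05,
                   max_gnomad_af=None, min_cadd=min_cadd)

    @classmethod
    def germline_default(cls, min_cadd: float = 15.0,
                         max_gnomad_af: float = 0.001) -> "FilterPolicy":
        return cls(origin=GERMLINE, min_ad=5, min_vaf=0.20,
                   max_gnomad_af=max_gnomad_af, min_cadd=min_cadd)


@dataclass
class FilterTally:
    """Per-criterion drop counts from one `apply_filters` pass."""

    n_input: int = 0
    n_retained: int = 0
    dropped: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                **{f"dropped_{k}": v for k, v in sorted(self.dropped.items())}}


def normalize_allele(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Left-align and parsimony-trim an allele pair.

    Shared trailing bases are stripped first, then shared leading bases
    (advancing ``pos``), so indel dialect differences do not break joins.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _variant_type(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


def read_vcf(path: str | Path, origin: str,
             sample: Optional[str] = None) -> Iterator[AnnotatedVariant]:
    """Stream AnnotatedVariants from a VCF, one per (record, alt allele).

    AD/DP are taken from the FORMAT fields of the chosen sample column
    (default: first). Records without parseable depth fields are emitted
    with missing depths and counted in a warning summary.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    sample_idx = 0
    if sample is not None:
        try:
            sample_idx = vcf.samples.index(sample)
        except ValueError:
            raise ValueError(
                f"sample {sample!r} not in VCF {path}; has {vcf.samples}")

    n_missing_depth = 0
    for record in vcf:
        ad_row = None
        dp_row = None
        try:
            ad = record.format("AD")
            if ad is not None:
                ad_row = ad[sample_idx]
        except (KeyError, TypeError):
            ad_row = None
        try:
            dp = record.format("DP")
            if dp is not None:
                dp_row = dp[sample_idx]
        except (KeyError, TypeError):
            dp_row = None

        for alt_i, alt in enumerate(record.ALT):
            allele_depth = None
            total_depth = None
            if ad_row is not None and len(ad_row) > alt_i + 1:
                raw = int(ad_row[alt_i + 1])
                allele_depth = raw if raw >= 0 else None
            if dp_row is not None:
                raw = int(dp_row[0]) if hasattr(dp_row, "__len__") else int(dp_row)
                total_depth = raw if raw >= 0 else None
            if total_depth is None and ad_row is not None:
                vals = [int(x) for x in ad_row if int(x) >= 0]
                total_depth = sum(vals) if vals else None

            vaf = None
            if allele_depth is not None and total_depth and total_depth > 0:
                vaf = allele_depth / total_depth
            if allele_depth is None or total_depth is None:
                n_missing_depth += 1

            yield AnnotatedVariant(
                chrom=record.CHROM,
                pos=record.POS,
                ref=record.REF,
                alt=alt,
                vtype=_variant_type(record.REF, alt),
                origin=origin,
                allele_depth=allele_depth,
                total_depth=total_depth,
                vaf=vaf,
            )
    if n_missing_depth:
        logger.warning("%s: %d variant records lacked parseable AD/DP fields",
                       path, n_missing_depth)


def read_lookup_table(path: str | Path, value_name: str = "value",
                      numeric: bool = True) -> dict[tuple[str, int, str, str], object]:
    """Load a tab-separated (chrom, pos, ref, alt, value) table into a dict.

    Keys are parsimony-normalized. Malformed rows are skipped with a
    warning count in the log.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 5:
        raise ValueError(
            f"lookup table {path} needs >= 5 columns (chrom, pos, ref, alt, value)")
    table: dict[tuple[str, int, str, str], object] = {}
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            chrom, pos, ref, alt, value = row[0], int(row[1]), row[2], row[3], row[4]
            if numeric:
                value = float(value)
            if value is None or (numeric and value != value):  # NaN guard
                raise ValueError
            table[normalize_allele(str(chrom), pos, str(ref), str(alt))] = value
        except (TypeError, ValueError):
            n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d malformed rows (%s)", path, n_bad, value_name)
    return table


def annotate_variants(
    variants: Iterable[AnnotatedVariant],
    cadd_table: dict[tuple[str, int, str, str], float],
    gnomad_table: dict[tuple[str, int, str, str], float],
    gene_table: dict[tuple[str, int, str, str], str],
) -> Iterator[AnnotatedVariant]:
    """Attach CADD Phred, gnomAD AF, and gene symbol via normalized keys.

    Unmatched variants keep missing values and are tallied in the log.
    """
    misses = Counter()
    for v in variants:
        key = v.key
        cadd = cadd_table.get(key)
        af = gnomad_table.get(key)
        gene = gene_table.get(key)
        for name, hit in (("cadd", cadd), ("gnomad", af), ("gene", gene)):
            if hit is None:
                misses[name] += 1
        yield replace(v, cadd_phred=cadd, gnomad_af=af,
                      gene=str(gene) if gene is not None else None)
    if misses:
        logger.info("annotation misses: %s", dict(misses))


def apply_filters(
    variants: Iterable[AnnotatedVariant],
    policy: FilterPolicy,
) -> tuple[list[AnnotatedVariant], FilterTally]:
    """Retain variants passing the policy; tally drops per criterion.

    Missing gnomAD AF passes the rarity filter (absence from a population
    database is evidence of rarity); missing CADD fails whenever
    ``min_cadd > 0`` since deleteriousness is then unknowable.
    """
    tally = FilterTally()
    retained: list[AnnotatedVariant] = []
    for v in variants:
        tally.n_input += 1
        if v.origin != policy.origin:
            tally.dropped["origin_mismatch"] += 1
            continue
        if v.allele_depth is None or v.allele_depth < policy.min_ad:
            tally.dropped["allele_depth"] += 1
            continue
        if v.vaf is None or not v.vaf > policy.min_vaf:
            tally.dropped["vaf"] += 1
            continue
        if policy.max_gnomad_af is not None and v.gnomad_af is not None \
                and v.gnomad_af > policy.max_gnomad_af:
            tally.dropped["gnomad_af"] += 1
            continue
        if policy.min_cadd > 0 and v.cadd_phred is None:
            tally.dropped["cadd_missing"] += 1
            continue
        if v.cadd_phred is not None and v.cadd_phred < policy.min_cadd:
            tally.dropped["cadd"] += 1
            continue
        if v.gene is None:
            tally.dropped["no_gene"] += 1  # retained; cannot feed a gene score
        retained.append(v)
        tally.n_retained += 1
    return retained, tally


def write_audit_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write retained variants as a tab-separated audit file."""
    rows = [{
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "vtype": v.vtype, "origin": v.origin,
        "allele_depth": v.allele_depth, "total_depth": v.total_depth,
        "vaf": v.vaf, "cadd_phred": v.cadd_phred,
        "gnomad_af": v.gnomad_af, "gene": v.gene,
    } for v in variants]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_audit_table(path: str | Path) -> list[AnnotatedVariant]:
    """Re-load an audit file written by `write_audit_table`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(AnnotatedVariant(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), vtype=str(row.vtype), origin=str(row.origin),
            allele_depth=None if pd.isna(row.allele_depth) else int(row.allele_depth),
            total_depth=None if pd.isna(row.total_depth) else int(row.total_depth),
            vaf=None if pd.isna(row.vaf) else float(row.vaf),
            cadd_phred=None if pd.isna(row.cadd_phred) else float(row.cadd_phred),
            gnomad_af=None if pd.isna(row.gnomad_af) else float(row.gnomad_af),
            gene=None if pd.isna(row.gene) else str(row.gene),
        ))
    return out
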