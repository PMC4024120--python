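"""Cohort variant data model and I/O.

Normalizes heterogeneous caller outputs (VCF or annotated TSV tables)
into one cohort model: one :class:`AnnotatedVariant` per sample, caller
and site, carrying the functional/frequency annotations consumed by the
filter cascade and the per-call quality metrics consumed by the quality
vote.  Variant positions are 1-based (VCF convention); missing values
(no database frequency for a novel variant, absent quality metrics) are
retained, never dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REGION_CLASSES = frozenset(
    {"exonic", "splicing", "intronic", "intergenic", "utr"}
)
FUNCTION_CLASSES = frozenset(
    {
        "synonymous",
        "nonsynonymous",
        "stopgain",
        "frameshift_indel",
        "inframe_indel",
        "splicing",
        "other",
    }
)

_ALLELE_CHARS = frozenset("ACGT")


class CallsetError(ValueError):
    """Malformed call set or inconsistent cohort table."""


@dataclass(frozen=True)
class SiteQuality:
    """Per-call quality metrics feeding the quality vote.

    depth          read count at the position
    nra_fraction   fraction of reads supporting the non-reference allele
    mqv_ref        mean quality value of reference-supporting reads
    mqv_alt        mean quality value of variant-supporting reads

    Any field may be None (missing); missingness is preserved through I/O
    and handled explicitly by the filter cascade.
    """

    depth: int | None = None
    nra_fraction: float | None = None
    mqv_ref: float | None = None
    mqv_alt: float | None = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise CallsetError(f"depth must be >= 0, got {self.depth}")
        if self.nra_fraction is not None and not 0.0 <= self.nra_fraction <= 1.0:
            raise CallsetError(
                f"nra_fraction must be in [0, 1], got {self.nra_fraction}"
            )
        for name in ("mqv_ref", "mqv_alt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CallsetError(f"{name} must be >= 0, got {v}")


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce (pos, ref, alt) to the minimal left-shifted representation.

    Trims the shared suffix then the shared prefix (keeping at least one
    base of each allele), so indels reported differently by two callers
    compare equal.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant in one sample from one caller, with annotations."""

    sample_id: str
    caller_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    region_class: str = "exonic"
    function_class: str = "other"
    pop_af: float | None = None  # reference-population frequency; None = novel
    quality: SiteQuality = field(default_factory=SiteQuality)

    def __post_init__(self) -> None:
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or (
                not set(allele) <= _ALLELE_CHARS and not allele.startswith("<")
            ):
                raise CallsetError(f"invalid {name} allele {allele!r}")
        if self.region_class not in REGION_CLASSES:
            raise CallsetError(f"unknown region_class {self.region_class!r}")
        if self.function_class not in FUNCTION_CLASSES:
            raise CallsetError(f"unknown function_class {self.function_class!r}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise CallsetError(f"pop_af must be in [0, 1], got {self.pop_af}")
        if self.pos < 1:
            raise CallsetError(f"pos must be >= 1, got {self.pos}")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Normalized (chrom, pos, ref, alt) — caller-comparable identity."""
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)

    @property
    def sample_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id,) + self.site_key

    def normalized(self) -> "AnnotatedVariant":
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        if (pos, ref, alt) == (self.pos, self.ref, self.alt):
            return self
        return replace(self, pos=pos, ref=ref, alt=alt)


@dataclass
class CohortCallTable:
    """All calls of one caller (or a merged set) over one cohort batch."""

    variants: list[AnnotatedVariant]
    samples: list[str]
    batch_id: str = "batch1"

    def __post_init__(self) -> None:
        if not self.samples:
            raise CallsetError("cohort must contain at least one sample")
        roster = set(self.samples)
        seen: set[tuple] = set()
        for v in self.variants:
            if v.sample_id not in roster:
                raise CallsetError(
                    f"variant sample {v.sample_id!r} not in batch roster"
                )
            k = (v.sample_id, v.caller_id) + v.site_key
            if k in seen:
                raise CallsetError(f"duplicate call record {k}")
            seen.add(k)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, variants: list[AnnotatedVariant]) -> "CohortCallTable":
        return CohortCallTable(
            variants=list(variants), samples=list(self.samples), batch_id=self.batch_id
        )

    def carriers(self, site_key: tuple[str, int, str, str]) -> set[str]:
        """Samples with >=1 call of the site by any caller."""
        return {v.sample_id for v in self.variants if v.site_key == site_key}


# ---------------------------------------------------------------------------
# Annotated-TSV dialect
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample",
    "caller",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "region_class",
    "function_class",
    "pop_af",
    "depth",
    "nra_fraction",
    "mqv_ref",
    "mqv_alt",
]


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def _opt_int(x) -> int | None:
    f = _opt_float(x)
    return None if f is None else int(round(f))


def read_callset_tsv(path: str | Path) -> list[AnnotatedVariant]:
    """Read the documented annotated-TSV dialect (one call per row)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str, "caller": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise CallsetError(f"{path}: missing required columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        gene = row.gene if isinstance(row.gene, str) and row.gene not in (".", "") else None
        out.append(
            AnnotatedVariant(
                sample_id=row.sample,
                caller_id=row.caller,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=gene,
                region_class=row.region_class,
                function_class=row.function_class,
                pop_af=_opt_float(row.pop_af),
                quality=SiteQuality(
                    depth=_opt_int(row.depth),
                    nra_fraction=_opt_float(row.nra_fraction),
                    mqv_ref=_opt_float(row.mqv_ref),
                    mqv_alt=_opt_float(row.mqv_alt),
                ),
            ).normalized()
        )
    return out


def to_frame(variants: list[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        q = v.quality
        rows.append(
            {
                "sample": v.sample_id,
                "caller": v.caller_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene if v.gene is not None else "",
                "region_class": v.region_class,
                "function_class": v.function_class,
                "pop_af": np.nan if v.pop_af is None else v.pop_af,
                "depth": np.nan if q.depth is None else q.depth,
                "nra_fraction": np.nan if q.nra_fraction is None else q.nra_fraction,
                "mqv_ref": np.nan if q.mqv_ref is None else q.mqv_ref,
                "mqv_alt": np.nan if q.mqv_alt is None else q.mqv_alt,
            }
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_callset_tsv(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Write the annotated-TSV dialect; fractions at 6-decimal precision."""
    df = to_frame(variants)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source={caller}
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">
##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Reference-population allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=MQVR,Number=1,Type=Float,Description="Mean quality value, reference reads">
##FORMAT=<ID=MQVA,Number=1,Type=Float,Description="Mean quality value, variant reads">
"""


def read_callset_vcf(
    path: str | Path, caller_id: str | None = None
) -> list[AnnotatedVariant]:
    """Read a (possibly multi-sample) VCF call set.

    nra_fraction is computed from per-genotype allele depths (AD) as
    alt / (ref + alt); records without AD are loaded with quality fields
    missing (a warning is logged), never dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if caller_id is None:
        caller_id = "unknown"
        for line in vcf.raw_header.splitlines():
            if line.startswith("##source="):
                caller_id = line.split("=", 1)[1]
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        region = rec.INFO.get("REGION", "exonic")
        func = rec.INFO.get("FUNC", "other")
        pop_af = rec.INFO.get("POP_AF")
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        try:
            mqvr = rec.format("MQVR")
            mqva = rec.format("MQVA")
        except KeyError:
            mqvr = mqva = None
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        for i, sample in enumerate(samples):
            if gts[i] in (0, 2):
                continue
            depth = nra = None
            if ad is not None and ad[i][0] >= 0:
                ref_n, alt_n = int(ad[i][0]), int(ad[i][1])
                total = ref_n + alt_n
                if total > 0:
                    depth, nra = total, alt_n / total
            else:
                log.warning(
                    "%s %s:%s %s: no allele-depth information for %s; "
                    "quality fields marked missing",
                    path,
                    rec.CHROM,
                    rec.POS,
                    rec.ALT[0],
                    sample,
                )
            q = SiteQuality(
                depth=depth,
                nra_fraction=nra,
                mqv_ref=_fmt_value(mqvr, i),
                mqv_alt=_fmt_value(mqva, i),
            )
            out.append(
                AnnotatedVariant(
                    sample_id=sample,
                    caller_id=caller_id,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    gene=gene,
                    region_class=region,
                    function_class=func,
                    pop_af=None if pop_af is None else float(pop_af),
                    quality=q,
                ).normalized()
            )
    return out


def _fmt_value(arr, i) -> float | None:
    if arr is None:
        return None
    v = float(arr[i][0]) if arr.ndim > 1 else float(arr[i])
    return None if math.isnan(v) else v


def write_callset_vcf(
    variants: list[AnnotatedVariant],
    samples: list[str],
    path: str | Path,
    caller_id: str | None = None,
) -> None:
    """Write calls as a multi-sample VCF v4.2 (GT:AD:DP:MQVR:MQVA)."""
    if caller_id is None:
        callers = {v.caller_id for v in variants}
        caller_id = callers.pop() if len(callers) == 1 else "merged"
    by_site: dict[tuple, list[AnnotatedVariant]] = {}
    for v in variants:
        by_site.setdefault(v.site_key, []).append(v)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(caller=caller_id))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for key in sorted(by_site, key=lambda k: (k[0], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            group = by_site[key]
            rep = group[0]
            info = [
                f"REGION={rep.region_class}",
                f"FUNC={rep.function_class}",
            ]
            if rep.gene is not None:
                info.insert(0, f"GENE={rep.gene}")
            if rep.pop_af is not None:
                info.append(f"POP_AF={rep.pop_af:.6f}")
            per_sample = {v.sample_id: v for v in group}
            cols = []
            for s in samples:
                v = per_sample.get(s)
                if v is None:
                    cols.append("0/0:.:.:.:.")
                    continue
                q = v.quality
                if q.depth is not None and q.nra_fraction is not None:
                    alt_n = int(round(q.depth * q.nra_fraction))
                    ad = f"{q.depth - alt_n},{alt_n}"
                    dp = str(q.depth)
                    gt = "1/1" if q.nra_fraction >= 0.7 else "0/1"
                else:
                    ad, dp, gt = ".", ".", "0/1"
                mr = "." if q.mqv_ref is None else f"{q.mqv_ref:.2f}"
                ma = "." if q.mqv_alt is None else f"{q.mqv_alt:.2f}"
                cols.append(f"{gt}:{ad}:{dp}:{mr}:{ma}")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                + ";".join(info)
                + "\tGT:AD:DP:MQVR:MQVA\t"
                + "\t".join(cols)
                + "\n"
            )


def read_callset(
    path: str | Path,
    dialect: str,
    caller_id: str | None = None,
) -> list[AnnotatedVariant]:
    """Dispatch to the VCF or annotated-TSV reader."""
    if dialect == "vcf":
        return read_callset_vcf(path, caller_id=caller_id)
    if dialect == "annotated_tsv":
        return read_callset_tsv(path)
    raise CallsetError(f"unknown call set dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Depth tracks (BedGraph-style TSV)
# ---------------------------------------------------------------------------


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a per-sample BedGraph-style depth track (chrom, start, end, depth)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": int, "end": int, "depth": int},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise CallsetError(f"{path}: depth track interval with end <= start")
    return df


def write_depth_track(depths: dict[str, np.ndarray], offsets: dict[str, int],
                      path: str | Path) -> None:
    """Run-length encode per-contig depth arrays to BedGraph-style TSV.

    ``depths[chrom]`` is the per-base depth from ``offsets[chrom]`` on.
    """
    with open(path, "w") as fh:
        for chrom in sorted(depths):
            arr = np.asarray(depths[chrom])
            off = offsets[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{off + s}\t{off + e}\t{int(arr[s])}\n")


def depth_vector(track: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base depth over [start, end) from a BedGraph-style track."""
    out = np.zeros(end - start, dtype=int)
    sel = track[(track["chrom"] == chrom) & (track["end"] > start) & (track["start"] < end)]
    for row in sel.itertuples(index=False):
        a, b = max(row.start, start), min(row.end, end)
        out[a - start : b - start] = row.depth
    return out


# ---------------------------------------------------------------------------
# Pre-filter
# ---------------------------------------------------------------------------


def build_mask(intervals: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    """Build a per-chromosome interval tree from 0-based half-open intervals."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def prefilter_callset(
    table: CohortCallTable,
    mappability_mask: list[tuple[str, int, int]] | dict[str, IntervalTree] | None = None,
    min_depth_any_sample: int = 10,
) -> CohortCallTable:
    """Remove sites in low-mappability regions or without one well-covered sample.

    A site survives iff it lies outside every masked interval and at
    least one sample's call reaches ``min_depth_any_sample`` reads.
    Sites whose depth is missing in every sample are retained (the depth
    condition cannot be asserted either way).
    """
    if mappability_mask is None:
        trees: dict[str, IntervalTree] = {}
    elif isinstance(mappability_mask, dict):
        trees = mappability_mask
    else:
        trees = build_mask(mappability_mask)

    by_site: dict[tuple, list[AnnotatedVariant]] = {}
    for v in table.variants:
        by_site.setdefault(v.site_key, []).append(v)

    keep: list[AnnotatedVariant] = []
    for key, group in by_site.items():
        chrom, pos, _, _ = key
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(pos - 1):  # 1-based -> 0-based
            continue
        depths = [v.quality.depth for v in group if v.quality.depth is not None]
        if depths and max(depths) < min_depth_any_sample:
            continue
        keep.extend(group)
    order = {id(v): i for i, v in enumerate(table.variants)}
    keep.sort(key=lambda v: order[id(v)])
    return table.subset(keep)
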