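"""Dual-caller concordance and confirmation accounting.

Running two variant callers in parallel and comparing their outputs
against confirmation (Sanger) results separates real variants from
caller-specific artifacts: real variants are typically called by both
packages, while each caller's false positives tend to be its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .variants import AnnotatedVariant

#: (sample, chrom, pos, ref, alt) after allele normalization
VariantKey = tuple[str, str, int, str, str]


@dataclass
class ConcordanceRecord:
    key: VariantKey
    detected_by: set[str]
    truth_status: str = "unknown"  # real | false_positive | unknown
    quality_by_caller: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.detected_by:
            raise ValueError("record must be detected by at least one caller")
        if self.truth_status not in ("real", "false_positive", "unknown"):
            raise ValueError(f"bad truth_status {self.truth_status!r}")


@dataclass
class TruthSet:
    """Confirmation outcomes keyed by (sample, chrom, pos, ref, alt)."""

    entries: dict[VariantKey, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values()} - {"real", "false_positive"}
        if bad:
            raise ValueError(f"truth status must be real/false_positive, got {bad}")

    def real_keys(self) -> set[VariantKey]:
        return {k for k, v in self.entries.items() if v == "real"}

    def fp_keys(self) -> set[VariantKey]:
        return {k for k, v in self.entries.items() if v == "false_positive"}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
        entries = {
            (r.sample, r.chrom, int(r.pos), r.ref, r.alt): r.status
            for r in df.itertuples(index=False)
        }
        return cls(entries=entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"sample": k[0], "chrom": k[1], "pos": k[2], "ref": k[3], "alt": k[4],
             "status": v}
            for k, v in sorted(self.entries.items())
        ]
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "status"]
                     ).to_csv(path, sep="\t", index=False)


def merge_callsets(
    calls_a: list[AnnotatedVariant],
    calls_b: list[AnnotatedVariant],
    caller_a: str | None = None,
    caller_b: str | None = None,
    roster_a: set[str] | None = None,
    roster_b: set[str] | None = None,
) -> dict[VariantKey, ConcordanceRecord]:
    """Union two normalized call sets into per-variant concordance records.

    Caller labels default to the (single) caller_id found in each input.
    If explicit sample rosters are given they must match; otherwise the
    rosters observed in the two call sets are not compared (a caller may
    legitimately emit no call for a sample).
    """
    if roster_a is not None and roster_b is not None and roster_a != roster_b:
        only_a = sorted(roster_a - roster_b)
        only_b = sorted(roster_b - roster_a)
        raise ValueError(
            f"sample rosters differ: only in A {only_a}, only in B {only_b}"
        )
    caller_a = caller_a or _single_caller(calls_a, "caller_a")
    caller_b = caller_b or _single_caller(calls_b, "caller_b")
    records: dict[VariantKey, ConcordanceRecord] = {}
    for calls, label in ((calls_a, caller_a), (calls_b, caller_b)):
        for v in calls:
            key = v.sample_key
            rec = records.get(key)
            if rec is None:
                rec = ConcordanceRecord(key=key, detected_by={label})
                records[key] = rec
            else:
                rec.detected_by.add(label)
            rec.quality_by_caller[label] = v.quality
    return records


def _single_caller(calls: list[AnnotatedVariant], default: str) -> str:
    callers = {v.caller_id for v in calls}
    if len(callers) == 1:
        return callers.pop()
    return default


def annotate_truth(
    records: dict[VariantKey, ConcordanceRecord], truth: TruthSet
) -> None:
    for key, rec in records.items():
        rec.truth_status = truth.entries.get(key, "unknown")


def _trunc1(x: float) -> float:
    return math.floor(x * 10.0) / 10.0


def miss_rate(truth: TruthSet, calls: list[AnnotatedVariant]) -> float:
    """Percent of confirmed-real variants absent from a call set.

    Truncated (not rounded) to one decimal: 3 of 105 missed gives 2.8,
    9 of 105 gives 8.5.
    """
    real = truth.real_keys()
    if not real:
        raise ValueError("truth set contains no confirmed-real variants")
    called = {v.sample_key for v in calls}
    missed = len(real - called)
    return _trunc1(100.0 * missed / len(real))


def caller_specific_false_positives(
    records: dict[VariantKey, ConcordanceRecord] | list[ConcordanceRecord],
    caller_a: str,
    caller_b: str,
) -> tuple[set[VariantKey], set[VariantKey], set[VariantKey]]:
    """Partition false-positive records by detecting caller."""
    recs = records.values() if isinstance(records, dict) else records
    fp_only_a: set[VariantKey] = set()
    fp_only_b: set[VariantKey] = set()
    fp_shared: set[VariantKey] = set()
    for rec in recs:
        if rec.truth_status != "false_positive":
            continue
        has_a, has_b = caller_a in rec.detected_by, caller_b in rec.detected_by
        if has_a and has_b:
            fp_shared.add(rec.key)
        elif has_a:
            fp_only_a.add(rec.key)
        elif has_b:
            fp_only_b.add(rec.key)
    return fp_only_a, fp_only_b, fp_shared


def confirmation_split(
    records: dict[VariantKey, ConcordanceRecord] | list[ConcordanceRecord],
) -> tuple[int, int]:
    """(percent real, percent false positive) among fully confirmed records.

    Nearest whole percents constrained to sum to 100: the larger share
    absorbs the rounding residue.  59 real / 12 false of 71 gives (83, 17).
    """
    recs = list(records.values() if isinstance(records, dict) else records)
    unknown = [r.key for r in recs if r.truth_status == "unknown"]
    if unknown:
        raise ValueError(f"records without confirmation status: {sorted(unknown)}")
    if not recs:
        raise ValueError("no records to split")
    n_real = sum(r.truth_status == "real" for r in recs)
    p_real = int(math.floor(100.0 * n_real / len(recs) + 0.5))
    p_fp = int(math.floor(100.0 * (len(recs) - n_real) / len(recs) + 0.5))
    if p_real + p_fp != 100:
        if p_real >= p_fp:
            p_real = 100 - p_fp
        else:
            p_fp = 100 - p_real
    return p_real, p_fp


def records_to_frame(
    records: dict[VariantKey, ConcordanceRecord]
) -> pd.DataFrame:
    rows = [
        {
            "sample": k[0],
            "chrom": k[1],
            "pos": k[2],
            "ref": k[3],
            "alt": k[4],
            "detected_by": ",".join(sorted(r.detected_by)),
            "truth_status": r.truth_status,
        }
        for k, r in sorted(records.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "detected_by", "truth_status"],
    )
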