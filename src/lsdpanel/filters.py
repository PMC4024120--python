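"""Two-stage variant filter cascade.

Filter 1 keeps rare, potentially protein-altering variants: database
frequency <= 0.01 (missing counts as rare/novel), exonic or splicing
location, a protein-altering functional class, and cohort frequency
<= 4% of samples.  Filter 2 then separates real calls from artifacts by
a 3-of-4 quality vote on depth (>=20), non-reference-allele read
percentage (>=30), allele mean quality values (both >=15) and their
absolute difference (<=5).  Calls with any metric near its threshold
are flagged borderline; a condition whose metric is missing counts as
not satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .variants import AnnotatedVariant, CohortCallTable, SiteQuality


@dataclass
class FilterConfig:
    pop_af_max: float = 0.01
    cohort_freq_max: float = 0.04
    allowed_regions: frozenset[str] = frozenset({"exonic", "splicing"})
    allowed_classes: frozenset[str] = frozenset(
        {"nonsynonymous", "stopgain", "frameshift_indel", "inframe_indel", "splicing"}
    )
    min_depth: int = 20
    min_nra_pct: float = 30.0
    min_mqv: float = 15.0
    max_mqv_diff: float = 5.0
    min_votes: int = 3
    borderline_margin: float = 0.10  # relative fraction of each threshold
    # cohort frequency denominator: carrier samples (default) or alleles
    cohort_freq_mode: str = "carriers"
    missing_pop_af_is_rare: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.pop_af_max < 1:
            raise ValueError("pop_af_max must be in (0, 1)")
        if not 0 < self.cohort_freq_max < 1:
            raise ValueError("cohort_freq_max must be in (0, 1)")
        if not 0 <= self.min_votes <= 4:
            raise ValueError("min_votes must be in [0, 4]")
        if self.borderline_margin < 0:
            raise ValueError("borderline_margin must be >= 0")
        if self.cohort_freq_mode not in ("carriers", "alleles"):
            raise ValueError("cohort_freq_mode must be 'carriers' or 'alleles'")
        self.allowed_regions = frozenset(self.allowed_regions)
        self.allowed_classes = frozenset(self.allowed_classes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["allowed_regions"] = sorted(self.allowed_regions)
        data["allowed_classes"] = sorted(self.allowed_classes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class Filter1Decision:
    key: tuple
    af_rare: bool
    region_ok: bool
    class_ok: bool
    cohort_rare: bool

    @property
    def passed(self) -> bool:
        return self.af_rare and self.region_ok and self.class_ok and self.cohort_rare


@dataclass(frozen=True)
class Filter2Decision:
    key: tuple
    depth_ok: bool
    nra_ok: bool
    mqv_ok: bool
    diff_ok: bool
    borderline: bool
    missing_conditions: int

    @property
    def votes(self) -> int:
        return sum((self.depth_ok, self.nra_ok, self.mqv_ok, self.diff_ok))

    def passed(self, min_votes: int = 3) -> bool:
        return self.votes >= min_votes


@dataclass
class CascadeReport:
    n_input: int
    n_after_filter1: int
    n_after_filter2: int
    borderline_keys: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_input >= self.n_after_filter1 >= self.n_after_filter2 >= 0:
            raise ValueError("stage counts must be non-increasing")

    @property
    def implied_fp_rate(self) -> int | None:
        """Percent of Filter-1 survivors judged false positive by Filter 2."""
        if self.n_after_filter1 == 0:
            return None
        return implied_fp_rate(self.n_after_filter1, self.n_after_filter2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "after_filter1", "after_filter2"],
                "count": [self.n_input, self.n_after_filter1, self.n_after_filter2],
            }
        )


def cohort_nra_frequency(
    table: CohortCallTable,
    key: tuple[str, int, str, str],
    mode: str = "carriers",
) -> float:
    """Frequency of a variant in the study group.

    Default: carrier samples (>=1 call by any caller) / cohort samples.
    ``mode='alleles'`` counts two alleles for calls whose NRA fraction
    reaches the homozygous band (>=0.7), over 2N chromosomes.
    """
    if table.n_samples == 0:
        raise ValueError("cohort has no samples")
    if mode == "carriers":
        return len(table.carriers(key)) / table.n_samples
    best: dict[str, float] = {}
    for v in table.variants:
        if v.site_key == key and v.quality.nra_fraction is not None:
            best[v.sample_id] = max(
                best.get(v.sample_id, 0.0), v.quality.nra_fraction
            )
    for s in table.carriers(key) - set(best):
        best[s] = 0.0
    alleles = sum(2 if f >= 0.7 else 1 for f in best.values())
    return alleles / (2 * table.n_samples)


def apply_filter1(
    v: AnnotatedVariant, cohort_freq: float, cfg: FilterConfig | None = None
) -> Filter1Decision:
    """Annotation/frequency filter: all four criteria must hold."""
    cfg = cfg or FilterConfig()
    if not 0.0 <= cohort_freq <= 1.0:
        raise ValueError(f"cohort_freq must be in [0, 1], got {cohort_freq}")
    if v.pop_af is None:
        af_rare = cfg.missing_pop_af_is_rare
    else:
        af_rare = v.pop_af <= cfg.pop_af_max
    return Filter1Decision(
        key=(v.sample_id, v.caller_id) + v.site_key,
        af_rare=af_rare,
        region_ok=v.region_class in cfg.allowed_regions,
        class_ok=v.function_class in cfg.allowed_classes,
        cohort_rare=cohort_freq <= cfg.cohort_freq_max,
    )


def _near(value: float, threshold: float, margin: float) -> bool:
    return abs(value - threshold) <= margin * threshold


def apply_filter2(
    q: SiteQuality, cfg: FilterConfig | None = None, key: tuple = ()
) -> Filter2Decision:
    """Quality vote over the four per-call conditions.

    A condition evaluated on a missing metric counts as not satisfied
    and increments ``missing_conditions``.  ``borderline`` is set when
    any evaluated metric lies within ``borderline_margin`` (relative) of
    its threshold — the calls the confirmation study singled out as
    "near the limit".
    """
    cfg = cfg or FilterConfig()
    missing = 0
    near = False

    if q.depth is None:
        depth_ok = False
        missing += 1
    else:
        depth_ok = q.depth >= cfg.min_depth
        near |= _near(q.depth, cfg.min_depth, cfg.borderline_margin)

    if q.nra_fraction is None:
        nra_ok = False
        missing += 1
    else:
        pct = 100.0 * q.nra_fraction
        nra_ok = pct >= cfg.min_nra_pct
        near |= _near(pct, cfg.min_nra_pct, cfg.borderline_margin)

    if q.mqv_ref is None or q.mqv_alt is None:
        mqv_ok = False
        diff_ok = False
        missing += 2
    else:
        mqv_ok = q.mqv_ref >= cfg.min_mqv and q.mqv_alt >= cfg.min_mqv
        diff = abs(q.mqv_ref - q.mqv_alt)
        diff_ok = diff <= cfg.max_mqv_diff
        near |= _near(min(q.mqv_ref, q.mqv_alt), cfg.min_mqv, cfg.borderline_margin)
        near |= _near(diff, cfg.max_mqv_diff, cfg.borderline_margin)

    return Filter2Decision(
        key=key,
        depth_ok=depth_ok,
        nra_ok=nra_ok,
        mqv_ok=mqv_ok,
        diff_ok=diff_ok,
        borderline=near,
        missing_conditions=missing,
    )


def run_cascade(
    table: CohortCallTable, cfg: FilterConfig | None = None
) -> tuple[CohortCallTable, CascadeReport, pd.DataFrame]:
    """Apply Filter 1 then Filter 2 over a cohort call table.

    Returns the surviving table, the stage-count report, and a
    per-variant decision frame with every criterion/condition flag.
    """
    cfg = cfg or FilterConfig()
    freq_cache: dict[tuple, float] = {}
    rows = []
    survivors = []
    n_after_f1 = 0
    borderline: list[tuple] = []
    for v in table.variants:
        sk = v.site_key
        if sk not in freq_cache:
            freq_cache[sk] = cohort_nra_frequency(table, sk, mode=cfg.cohort_freq_mode)
        d1 = apply_filter1(v, freq_cache[sk], cfg)
        row = {
            "sample": v.sample_id,
            "caller": v.caller_id,
            "chrom": sk[0],
            "pos": sk[1],
            "ref": sk[2],
            "alt": sk[3],
            "cohort_freq": freq_cache[sk],
            "af_rare": d1.af_rare,
            "region_ok": d1.region_ok,
            "class_ok": d1.class_ok,
            "cohort_rare": d1.cohort_rare,
            "filter1_pass": d1.passed,
        }
        if d1.passed:
            n_after_f1 += 1
            d2 = apply_filter2(v.quality, cfg, key=d1.key)
            row.update(
                depth_ok=d2.depth_ok,
                nra_ok=d2.nra_ok,
                mqv_ok=d2.mqv_ok,
                diff_ok=d2.diff_ok,
                votes=d2.votes,
                missing_conditions=d2.missing_conditions,
                borderline=d2.borderline,
                filter2_pass=d2.passed(cfg.min_votes),
            )
            if d2.borderline:
                borderline.append(d1.key)
            if d2.passed(cfg.min_votes):
                survivors.append(v)
        else:
            row.update(
                depth_ok=False,
                nra_ok=False,
                mqv_ok=False,
                diff_ok=False,
                votes=0,
                missing_conditions=0,
                borderline=False,
                filter2_pass=False,
            )
        rows.append(row)
    report = CascadeReport(
        n_input=len(table.variants),
        n_after_filter1=n_after_f1,
        n_after_filter2=len(survivors),
        borderline_keys=borderline,
    )
    return table.subset(survivors), report, pd.DataFrame(rows)


def implied_fp_rate(n_before: int, n_after: int) -> int:
    """False-positive percentage implied by a filtering stage.

    round(100 * removed / input) to the nearest whole percent (half
    rounds up), e.g. 219 -> 77 gives 65.
    """
    if n_before <= 0:
        raise ValueError("n_before must be > 0")
    if not n_before >= n_after >= 0:
        raise ValueError("need n_before >= n_after >= 0")
    return int(math.floor(100.0 * (n_before - n_after) / n_before + 0.5))
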