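"""Exon-dosage CNV detection and coverage QC from read-depth tracks.

Gross (whole-exon) deletions and duplications are invisible to per-base
variant calling but show up as dosage shifts in the exon coverage peak
area (the sum of per-base depth over the exon): a heterozygous deletion
halves the area, a homozygous deletion sends it to ~zero, a heterozygous
duplication raises it to ~1.5x.  Peak areas are normalized by a robust
median-of-ratios scheme (cohort-median reference per exon, per-sample
median scale factor) so library-size differences cancel, and contiguous
runs of exons whose dosage ratio falls in one state band are emitted as
single CNV calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ExonTarget, PanelDesign


@dataclass
class ExonCoverageProfile:
    """Per-base depth of one sample over one exon target."""

    sample_id: str
    exon: ExonTarget
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.size != self.exon.length:
            raise ValueError(
                f"depth vector length {self.depths.size} != exon length {self.exon.length}"
            )
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def area(self) -> int:
        return int(self.depths.sum())


def exon_peak_area(depths: np.ndarray) -> int:
    """Coverage peak area of an exon: the sum of its per-base depths."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    return int(depths.sum())


def area_matrix(profiles: list[ExonCoverageProfile]) -> pd.DataFrame:
    """samples x exons matrix of peak areas; columns are (gene, exon_id)."""
    rows: dict[str, dict[tuple, int]] = {}
    for p in profiles:
        rows.setdefault(p.sample_id, {})[p.exon.key] = p.area
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["gene", "exon_id"])
    return df.sort_index(axis=1)


@dataclass
class DosageTable:
    """Normalized dosage ratios with their normalization by-products.

    ``ratios`` is samples x exons; non-evaluable exons (cohort median
    area below the floor) hold NaN throughout.
    """

    ratios: pd.DataFrame
    reference_area: pd.Series
    scale_factors: pd.Series
    evaluable: pd.Series


def normalize_and_ratio(
    areas: pd.DataFrame, floor_area: float | pd.Series = 0.0
) -> DosageTable:
    """Median-of-ratios dosage normalization of a samples x exons area matrix.

    Per-sample size factors are the median, over exons with positive
    area in every sample, of (sample area / geometric-mean reference);
    the dosage reference per exon is the cohort median of size-corrected
    areas, and ratio(s, e) = corrected area / reference.  The
    geometric-mean reference makes the ratios exactly invariant to
    rescaling any single sample's areas (library-size effects cancel).
    Exons whose cohort-median area falls below ``floor_area`` (scalar,
    or per-exon Series, e.g. 20x mean depth) are marked non-evaluable.
    """
    if areas.shape[0] < 3:
        raise ValueError("insufficient cohort for median reference (need >= 3 samples)")
    median0 = areas.median(axis=0)
    if np.isscalar(floor_area):
        floor = pd.Series(float(floor_area), index=areas.columns)
    else:
        floor = floor_area.reindex(areas.columns)
    evaluable = median0 >= floor.where(floor > 0, other=0.0)
    evaluable &= median0 > 0
    if not evaluable.any():
        raise ValueError("no evaluable exons (cohort median below floor everywhere)")
    sf_cols = areas.columns[evaluable & (areas > 0).all(axis=0)]
    if len(sf_cols) > 0:
        log_ref = np.log(areas[sf_cols]).mean(axis=0)
        scale = np.exp(np.log(areas[sf_cols]).sub(log_ref, axis=1).median(axis=1))
    else:  # every evaluable exon has a zero somewhere: fall back to medians
        ev_cols = areas.columns[evaluable]
        scale = areas[ev_cols].div(median0[ev_cols], axis=1).median(axis=1)
    scaled = areas.div(scale, axis=0)
    reference = scaled.median(axis=0)
    ratios = scaled.div(reference, axis=1)
    ratios.loc[:, ~evaluable] = np.nan
    reference = reference.where(evaluable)
    return DosageTable(
        ratios=ratios, reference_area=reference, scale_factors=scale, evaluable=evaluable
    )


@dataclass
class CnvConfig:
    """Dosage-ratio state bands, centered on 0.5 / 0 / 1.5 expectations."""

    het_del: tuple[float, float] = (0.35, 0.65)
    hom_del: tuple[float, float] = (0.0, 0.15)
    het_dup: tuple[float, float] = (1.35, 1.65)
    min_consecutive: int = 1
    floor_mean_depth: float = 20.0  # exons below this cohort-median depth: non-evaluable

    def state_of(self, ratio: float) -> str:
        if np.isnan(ratio):
            return "non_evaluable"
        if self.hom_del[0] <= ratio <= self.hom_del[1]:
            return "hom_del"
        if self.het_del[0] <= ratio <= self.het_del[1]:
            return "het_del"
        if self.het_dup[0] <= ratio <= self.het_dup[1]:
            return "het_dup"
        return "normal"


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    gene: str
    first_exon: int
    last_exon: int
    state: str  # het_del | hom_del | het_dup
    mean_ratio: float

    @property
    def exon_range(self) -> tuple[int, ...]:
        return tuple(range(self.first_exon, self.last_exon + 1))


def call_gross_indels(
    dosage: DosageTable | pd.DataFrame, cfg: CnvConfig | None = None
) -> list[CnvCall]:
    """Emit maximal runs of consecutive same-state exons as CNV calls.

    Non-evaluable exons and exons outside every band (``normal``) break
    runs; ordinal gaps in a gene's evaluable exons also break runs, so a
    call's exon range is always contiguous.
    """
    cfg = cfg or CnvConfig()
    ratios = dosage.ratios if isinstance(dosage, DosageTable) else dosage
    calls: list[CnvCall] = []
    genes = ratios.columns.get_level_values("gene").unique()
    for sample_id, row in ratios.iterrows():
        for gene in genes:
            sub = row[gene].sort_index()
            run_state = None
            run_exons: list[int] = []
            run_ratios: list[float] = []

            def flush() -> None:
                if run_state in ("het_del", "hom_del", "het_dup") and len(
                    run_exons
                ) >= cfg.min_consecutive:
                    calls.append(
                        CnvCall(
                            sample_id=sample_id,
                            gene=gene,
                            first_exon=run_exons[0],
                            last_exon=run_exons[-1],
                            state=run_state,
                            mean_ratio=float(np.mean(run_ratios)),
                        )
                    )

            for exon_id, ratio in sub.items():
                state = cfg.state_of(ratio)
                contiguous = bool(run_exons) and exon_id == run_exons[-1] + 1
                if state == run_state and contiguous:
                    run_exons.append(exon_id)
                    run_ratios.append(ratio)
                else:
                    flush()
                    run_state = state
                    run_exons = [exon_id]
                    run_ratios = [ratio]
            flush()
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    rows = [
        {
            "sample": c.sample_id,
            "gene": c.gene,
            "first_exon": c.first_exon,
            "last_exon": c.last_exon,
            "state": c.state,
            "mean_ratio": round(c.mean_ratio, 4),
        }
        for c in sorted(calls, key=lambda c: (c.sample_id, c.gene, c.first_exon))
    ]
    return pd.DataFrame(
        rows, columns=["sample", "gene", "first_exon", "last_exon", "state", "mean_ratio"]
    )


@dataclass
class CoverageQcReport:
    """Coverage completeness against a depth threshold (default 20x)."""

    per_exon: pd.DataFrame  # gene, exon_id, pct_bases_ge_threshold
    per_gene: pd.DataFrame  # gene, n_gap_exons, gap_flag
    cohort_pct: float
    depth_threshold: int
    genes_gap_one_exon: list[str] = field(default_factory=list)
    genes_gap_multi_exon: list[str] = field(default_factory=list)


def coverage_qc(
    profiles: list[ExonCoverageProfile], depth_threshold: int = 20
) -> CoverageQcReport:
    """Percent of bases at/above a depth threshold, per exon, gene and cohort.

    A gene carries a gap flag iff at least one of its exons has any base
    below the threshold (in any sample); genes are listed separately by
    whether the gap affects exactly one exon or more than one.
    """
    per_exon_counts: dict[tuple, list[int]] = {}
    gene_of: dict[tuple, str] = {}
    total = covered = 0
    for p in profiles:
        k = p.exon.key
        ge = int((p.depths >= depth_threshold).sum())
        n = p.depths.size
        c = per_exon_counts.setdefault(k, [0, 0])
        c[0] += ge
        c[1] += n
        gene_of[k] = p.exon.gene
        covered += ge
        total += n
    exon_rows = [
        {
            "gene": gene_of[k],
            "exon_id": k[1],
            "pct_bases_ge_threshold": 100.0 * ge / n,
        }
        for k, (ge, n) in sorted(per_exon_counts.items())
    ]
    per_exon = pd.DataFrame(exon_rows, columns=["gene", "exon_id", "pct_bases_ge_threshold"])
    gene_rows = []
    one_exon, multi_exon = [], []
    for gene in per_exon["gene"].unique():
        sub = per_exon[per_exon["gene"] == gene]
        n_gap = int((sub["pct_bases_ge_threshold"] < 100.0).sum())
        gene_rows.append({"gene": gene, "n_gap_exons": n_gap, "gap_flag": n_gap >= 1})
        if n_gap == 1:
            one_exon.append(gene)
        elif n_gap > 1:
            multi_exon.append(gene)
    per_gene = pd.DataFrame(gene_rows, columns=["gene", "n_gap_exons", "gap_flag"])
    return CoverageQcReport(
        per_exon=per_exon,
        per_gene=per_gene,
        cohort_pct=100.0 * covered / total if total else 0.0,
        depth_threshold=depth_threshold,
        genes_gap_one_exon=sorted(one_exon),
        genes_gap_multi_exon=sorted(multi_exon),
    )


def profiles_from_tracks(
    panel: PanelDesign, tracks: dict[str, pd.DataFrame]
) -> list[ExonCoverageProfile]:
    """Build per-exon coverage profiles from per-sample BedGraph tracks."""
    from .variants import depth_vector

    profiles = []
    for sample_id, track in tracks.items():
        for exon in panel.exons:
            profiles.append(
                ExonCoverageProfile(
                    sample_id=sample_id,
                    exon=exon,
                    depths=depth_vector(track, exon.chrom, exon.start, exon.end),
                )
            )
    return profiles


def floor_areas(panel: PanelDesign, mean_depth: float = 20.0) -> pd.Series:
    """Per-exon area floor equal to ``mean_depth`` x exon length."""
    idx = pd.MultiIndex.from_tuples(
        [e.key for e in panel.exons], names=["gene", "exon_id"]
    )
    return pd.Series([mean_depth * e.length for e in panel.exons], index=idx)


def plot_gene_dosage(dosage: DosageTable, gene: str, path: str | Path) -> None:
    """Static per-gene dosage plot (one line per sample) for visual review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = dosage.ratios.xs(gene, axis=1, level="gene")
    fig, ax = plt.subplots(figsize=(6, 3))
    for sample_id, row in sub.iterrows():
        ax.plot(row.index, row.values, marker="o", lw=0.8, alpha=0.6, label=sample_id)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.axhline(0.5, color="r", lw=0.5, ls="--")
    ax.set_xlabel(f"{gene} exon")
    ax.set_ylabel("dosage ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
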