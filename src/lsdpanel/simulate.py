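"""Seeded synthetic cohorts with ground truth for every pipeline stage.

Emulates the statistical structure of a targeted gene-panel
resequencing study at desk scale: a miniature capture panel (default 10
genes x ~5 exons, 30 samples) with CpG-island coverage dropouts and
repeat-edge gaps; Poisson per-base coverage whose mean is scaled by copy
dosage (1 normal, 0.5 heterozygous deletion, ~0 homozygous deletion,
1.5 duplication); dual-caller call tables mixing planted true variants
(shared by both callers up to per-caller miss probabilities), common
polymorphisms with database frequencies, and caller-specific artifacts
concentrated on low-coverage exons whose quality metrics violate at
least two of the four quality-vote conditions.  A ground-truth manifest
records everything planted so every downstream stage is testable.

One global seed drives all stages through independent derived
substreams, so changing e.g. the artifact model does not perturb the
coverage simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import TruthSet
from .cnv import ExonCoverageProfile
from .panel import ExonTarget, PanelDesign
from .variants import AnnotatedVariant, CohortCallTable, SiteQuality

_LSD_GENES = [
    "GLB1", "CLN3", "HEXA", "NPC1", "ARSA", "IDUA", "GAA", "SMPD1", "TPP1",
    "GALC", "HEXB", "GBA", "NAGLU", "GUSB", "ARSB", "FUCA1", "NEU1", "CTNS",
    "GNPTAB", "MCOLN1",
]

_STAGE_PANEL, _STAGE_COVERAGE, _STAGE_CALLS = 0, 1, 2


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class DeletionPlanEntry:
    """One planted gross deletion/duplication spanning whole exons."""

    sample_id: str
    gene: str
    first_exon: int
    last_exon: int
    state: str  # het_del | hom_del | het_dup

    def multiplier(self) -> float:
        return {"het_del": 0.5, "hom_del": 0.0, "het_dup": 1.5}[self.state]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Per-caller miss probabilities default to the observed dual-caller
    detection failure rates (3/105 and 9/105 confirmed variants).
    """

    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (100, 250)
    n_samples: int = 30
    mean_depth: float = 200.0
    cpg_exon_fraction: float = 0.10
    cpg_depth_multiplier: float = 0.05
    repeat_edge_fraction: float = 0.05
    edge_gap_length: int = 20
    n_biallelic: int = 6
    n_monoallelic: int = 5
    n_polymorphisms: int = 20
    polymorphism_af_range: tuple[float, float] = (0.05, 0.5)
    artifact_rate: float = 3.0  # mean artifacts per sample per caller
    # fraction of true variants with one quality metric just past its
    # threshold (3-of-4 votes): the real calls an all-4 rule would lose
    true_borderline_rate: float = 0.09
    caller_a: str = "caller_a"
    caller_b: str = "caller_b"
    miss_prob_a: float = 3 / 105
    miss_prob_b: float = 9 / 105
    deletion_plan: list[DeletionPlanEntry] | None = None  # None -> default plan
    batch_id: str = "sim"

    def __post_init__(self) -> None:
        for name in (
            "cpg_exon_fraction",
            "cpg_depth_multiplier",
            "repeat_edge_fraction",
            "miss_prob_a",
            "miss_prob_b",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_biallelic + self.n_monoallelic > self.n_samples:
            raise ValueError("carrier archetypes exceed cohort size")

    @property
    def samples(self) -> list[str]:
        width = max(2, len(str(self.n_samples)))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


def simulate_panel(cfg: SimulationConfig, seed: int) -> PanelDesign:
    """Deterministic miniature capture panel with CpG/repeat-edge flags."""
    if cfg.n_genes < 1:
        raise ValueError("empty panel: n_genes must be >= 1")
    rng = _rng(seed, _STAGE_PANEL)
    names = list(_LSD_GENES[: cfg.n_genes])
    names += [f"LSDG{i}" for i in range(len(names) + 1, cfg.n_genes + 1)]
    exons: list[ExonTarget] = []
    pos = 10_000
    for gene in names:
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        for exon_id in range(1, n_ex + 1):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append(
                ExonTarget(
                    gene=gene,
                    exon_id=exon_id,
                    chrom="chr1",
                    start=pos,
                    end=pos + length,
                    cpg_island=bool(rng.random() < cfg.cpg_exon_fraction),
                    repeat_adjacent=bool(rng.random() < cfg.repeat_edge_fraction),
                )
            )
            pos += length + 500
        pos += 2_000
    return PanelDesign(genes=names, exons=exons)


def default_deletion_plan(
    panel: PanelDesign, samples: list[str]
) -> list[DeletionPlanEntry]:
    """Plant the study's observed CNV patterns: a two-exon heterozygous
    deletion, the same deletion homozygous in another sample, a
    single-exon heterozygous deletion, and a single-exon duplication."""

    def clean_exons(gene: str) -> list[ExonTarget]:
        return [e for e in panel.exons_of(gene) if not e.cpg_island]

    def consecutive_pair(gene: str) -> tuple[int, int] | None:
        ex = clean_exons(gene)
        ids = [e.exon_id for e in ex]
        for a, b in zip(ids, ids[1:]):
            if b == a + 1:
                return a, b
        return None

    taken: set[int] = set()

    def pick_sample(preferred: int) -> str:
        i = preferred % len(samples)
        while i in taken:
            i = (i + 1) % len(samples)
        taken.add(i)
        return samples[i]

    plan: list[DeletionPlanEntry] = []
    pair_gene = None
    for gene in panel.genes:
        pair = consecutive_pair(gene)
        if pair is not None:
            pair_gene = gene
            plan.append(
                DeletionPlanEntry(pick_sample(4), gene, pair[0], pair[1], "het_del")
            )
            plan.append(
                DeletionPlanEntry(pick_sample(10), gene, pair[0], pair[1], "hom_del")
            )
            break
    singles = [g for g in panel.genes if g != pair_gene and clean_exons(g)]
    if singles:
        e = clean_exons(singles[0])[0]
        plan.append(
            DeletionPlanEntry(pick_sample(16), singles[0], e.exon_id, e.exon_id, "het_del")
        )
    if len(singles) > 1:
        e = clean_exons(singles[1])[-1]
        plan.append(
            DeletionPlanEntry(pick_sample(20), singles[1], e.exon_id, e.exon_id, "het_dup")
        )
    return plan


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageSim:
    """Per-sample per-exon depth vectors plus a position lookup."""

    profiles: list[ExonCoverageProfile]
    _index: dict[tuple[str, tuple[str, int]], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {(p.sample_id, p.exon.key): p.depths for p in self.profiles}

    def depths_of(self, sample_id: str, exon_key: tuple[str, int]) -> np.ndarray:
        return self._index[(sample_id, exon_key)]

    def depth_at(self, sample_id: str, exon: ExonTarget, pos_1based: int) -> int:
        offset = pos_1based - 1 - exon.start
        return int(self._index[(sample_id, exon.key)][offset])


def simulate_coverage(
    panel: PanelDesign,
    cfg: SimulationConfig,
    seed: int,
    deletion_plan: list[DeletionPlanEntry] | None = None,
) -> CoverageSim:
    """Poisson per-base coverage scaled by copy dosage and capture dropouts.

    Per-base depth ~ Poisson(mean_depth * m), m = 1 normal / 0.5
    heterozygous deletion / 0 homozygous deletion / 1.5 duplication,
    multiplied by ``cpg_depth_multiplier`` on CpG-island exons;
    repeat-adjacent exons get zero-depth margins of ``edge_gap_length``.
    """
    if deletion_plan is None:
        deletion_plan = (
            cfg.deletion_plan
            if cfg.deletion_plan is not None
            else default_deletion_plan(panel, cfg.samples)
        )
    known = {e.key for e in panel.exons}
    del_mult: dict[tuple[str, str, int], float] = {}
    for entry in deletion_plan:
        for exon_id in range(entry.first_exon, entry.last_exon + 1):
            if (entry.gene, exon_id) not in known:
                raise ValueError(
                    f"deletion plan references unknown exon {entry.gene} exon {exon_id}"
                )
            del_mult[(entry.sample_id, entry.gene, exon_id)] = entry.multiplier()

    rng = _rng(seed, _STAGE_COVERAGE)
    profiles: list[ExonCoverageProfile] = []
    for sample in cfg.samples:
        for exon in panel.exons:
            m = del_mult.get((sample, exon.gene, exon.exon_id), 1.0)
            if exon.cpg_island:
                m *= cfg.cpg_depth_multiplier
            lam = cfg.mean_depth * m
            depths = rng.poisson(lam, size=exon.length) if lam > 0 else np.zeros(
                exon.length, dtype=int
            )
            if exon.repeat_adjacent:
                gap = min(cfg.edge_gap_length, exon.length // 2)
                depths[:gap] = 0
                depths[exon.length - gap :] = 0
            profiles.append(
                ExonCoverageProfile(sample_id=sample, exon=exon, depths=depths)
            )
    return CoverageSim(profiles=profiles)


# ---------------------------------------------------------------------------
# Call sets + manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedVariant:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    function_class: str
    zygosity: str  # het | hom
    role: str  # pathogenic | polymorphism
    emitted_by: tuple[str, ...]

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def sample_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PlantedArtifact:
    sample_id: str
    caller_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def sample_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GroundTruthManifest:
    """Everything planted, plus the outputs each stage is expected to produce."""

    samples: list[str]
    true_variants: list[PlantedVariant]
    artifacts: list[PlantedArtifact]
    cnvs: list[DeletionPlanEntry]
    expected_status: dict[str, tuple[str, str | None]]
    predictions: dict[tuple, list[str]]

    def truth_set(self) -> TruthSet:
        entries: dict[tuple, str] = {}
        for pv in self.true_variants:
            entries[pv.sample_key] = "real"
        for a in self.artifacts:
            entries[a.sample_key] = "false_positive"
        return TruthSet(entries=entries)

    def expected_status_counts(self) -> dict[str, int]:
        counts = {"diagnosed": 0, "carrier": 0, "undiagnosed": 0}
        for status, _ in self.expected_status.values():
            counts[status] += 1
        return counts

    def pathogenic_keys(self, caller: str | None = None) -> set[tuple]:
        return {
            pv.sample_key
            for pv in self.true_variants
            if pv.role == "pathogenic"
            and (caller is None or caller in pv.emitted_by)
        }


def _pick_position(
    rng: np.random.Generator,
    exon: ExonTarget,
    edge_gap: int,
    used: set[tuple[str, int]],
) -> int:
    lo, hi = exon.start, exon.end
    if exon.repeat_adjacent:
        gap = min(edge_gap, exon.length // 2 - 1)
        lo, hi = lo + gap, hi - gap
    for _ in range(1000):
        pos = int(rng.integers(lo, hi)) + 1  # 1-based
        if (exon.chrom, pos) not in used:
            used.add((exon.chrom, pos))
            return pos
    raise RuntimeError("could not find a free variant position")


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = bases[rng.integers(4)]
    while alt == ref:
        alt = bases[rng.integers(4)]
    return ref, alt


def _true_quality(
    rng: np.random.Generator,
    zygosity: str,
    depth: int,
    borderline: str | None = None,
) -> SiteQuality:
    """True-variant quality model: all four vote conditions satisfied,
    except that ``borderline`` names one condition drawn just past its
    threshold (a coverage dip, an under-represented indel, a shaky
    quality estimate) — still 3 of 4 votes."""
    if zygosity == "het":
        f = float(rng.normal(0.5, 0.05))
        while not 0.3 <= f <= 0.7:
            f = float(rng.normal(0.5, 0.05))
    else:
        f = float(rng.uniform(0.85, 1.0))
    mqv_ref = float(rng.uniform(20, 35))
    mqv_alt = float(np.clip(mqv_ref + rng.uniform(-4, 4), 15, None))
    if borderline == "depth":
        depth = int(rng.integers(10, 20))
    elif borderline == "nra":
        f = float(rng.uniform(0.25, 0.295))
    elif borderline == "mqv":
        mqv_alt = float(rng.uniform(10, 14.5))
        mqv_ref = mqv_alt + float(rng.uniform(0, 4))
    elif borderline == "diff":
        mqv_alt = mqv_ref + float(rng.uniform(5.5, 9))
    return SiteQuality(depth=depth, nra_fraction=f, mqv_ref=mqv_ref, mqv_alt=mqv_alt)


def _pick_borderline(
    rng: np.random.Generator, cfg: SimulationConfig, zygosity: str
) -> str | None:
    if rng.random() >= cfg.true_borderline_rate:
        return None
    choices = ["depth", "mqv", "diff"] + (["nra"] if zygosity == "het" else [])
    return choices[int(rng.integers(len(choices)))]


def _artifact_quality(rng: np.random.Generator) -> SiteQuality:
    """Quality metrics violating >= 2 of the four vote conditions."""
    n_viol = int(rng.integers(2, 5))
    violated = set(rng.choice(["depth", "nra", "mqv", "diff"], size=n_viol, replace=False))
    depth = int(rng.integers(3, 16)) if "depth" in violated else int(rng.integers(25, 80))
    nra = (
        float(rng.uniform(0.05, 0.28))
        if "nra" in violated
        else float(rng.uniform(0.32, 0.6))
    )
    if "mqv" in violated and "diff" in violated:
        mqv_ref = float(rng.uniform(2, 10))
        mqv_alt = mqv_ref + float(rng.uniform(6, 15))
    elif "mqv" in violated:
        low = float(rng.uniform(2, 12))
        mqv_ref, mqv_alt = low, float(np.clip(low + rng.uniform(-4, 4), 0, None))
    elif "diff" in violated:
        mqv_ref = float(rng.uniform(21, 30))
        mqv_alt = mqv_ref + float(rng.uniform(6, 10))
    else:
        mqv_ref = float(rng.uniform(16, 30))
        mqv_alt = float(np.clip(mqv_ref + rng.uniform(-4, 4), 15, None))
    return SiteQuality(depth=depth, nra_fraction=nra, mqv_ref=mqv_ref, mqv_alt=mqv_alt)


def _expected_statuses(
    planted: list[PlantedVariant],
) -> dict[str, tuple[str, str | None]]:
    """Expected diagnosis per sample, mirroring the triage qualification rule
    on the variants actually emitted by at least one caller.

    A homozygous pathogenic variant contributes two alleles; a
    heterozygous truncating variant one; a heterozygous missense
    qualifies (via the second-allele and prediction criteria) only when
    another emitted pathogenic variant shares its gene and sample.
    """
    by_sample_gene: dict[tuple[str, str], list[PlantedVariant]] = {}
    samples = set()
    for pv in planted:
        samples.add(pv.sample_id)
        if pv.role != "pathogenic" or not pv.emitted_by:
            continue
        by_sample_gene.setdefault((pv.sample_id, pv.gene), []).append(pv)
    status: dict[str, tuple[str, str | None]] = {}
    best: dict[str, tuple[int, str]] = {}
    for (sample, gene), pvs in by_sample_gene.items():
        alleles = 0
        for pv in pvs:
            if pv.zygosity == "hom":
                alleles += 2
            elif pv.function_class in ("stopgain", "frameshift_indel", "splicing"):
                alleles += 1
            elif len(pvs) >= 2:  # missense het qualifies via second allele
                alleles += 1
        cur = best.get(sample)
        if cur is None or alleles > cur[0]:
            best[sample] = (alleles, gene)
    for sample in samples:
        alleles, gene = best.get(sample, (0, None))
        if alleles >= 2:
            status[sample] = ("diagnosed", gene)
        elif alleles == 1:
            status[sample] = ("carrier", gene)
        else:
            status[sample] = ("undiagnosed", None)
    return status


def simulate_callsets(
    panel: PanelDesign,
    cfg: SimulationConfig,
    seed: int,
    coverage: CoverageSim | None = None,
    deletion_plan: list[DeletionPlanEntry] | None = None,
) -> tuple[CohortCallTable, CohortCallTable, GroundTruthManifest]:
    """Dual-caller call tables plus the ground-truth manifest.

    True variants are shared by both callers (each caller independently
    misses one with its configured probability) with quality from the
    true-variant model; artifacts are strictly caller-specific with
    quality from the artifact model; common polymorphisms carry their
    database frequency and are planted across samples under
    Hardy-Weinberg genotype proportions.
    """
    if deletion_plan is None:
        deletion_plan = (
            cfg.deletion_plan
            if cfg.deletion_plan is not None
            else default_deletion_plan(panel, cfg.samples)
        )
    if coverage is None:
        coverage = simulate_coverage(panel, cfg, seed, deletion_plan)
    rng = _rng(seed, _STAGE_CALLS)
    samples = cfg.samples
    used: set[tuple[str, int]] = set()
    deleted_genes: dict[str, set[str]] = {}
    for entry in deletion_plan:
        deleted_genes.setdefault(entry.sample_id, set()).add(entry.gene)

    clean_by_gene = {
        g: [e for e in panel.exons_of(g) if not e.cpg_island and e.length > 2 * cfg.edge_gap_length + 2]
        or panel.exons_of(g)
        for g in panel.genes
    }
    exon_by_key = {e.key: e for e in panel.exons}

    planted: list[PlantedVariant] = []
    predictions: dict[tuple, list[str]] = {}
    call_specs: list[tuple[PlantedVariant, SiteQuality, float | None]] = []

    def plant(sample: str, gene: str, zygosity: str, func: str, role: str,
              pop_af: float | None = None
              ) -> tuple[PlantedVariant, SiteQuality, float | None]:
        exon = clean_by_gene[gene][int(rng.integers(len(clean_by_gene[gene])))]
        pos = _pick_position(rng, exon, cfg.edge_gap_length, used)
        if func == "frameshift_indel":
            base, extra = _snv_alleles(rng)
            ref, alt = base + extra, base
        else:
            ref, alt = _snv_alleles(rng)
        depth = max(coverage.depth_at(sample, exon, pos), 1)
        q = _true_quality(rng, zygosity, depth, _pick_borderline(rng, cfg, zygosity))
        pv = PlantedVariant(
            sample_id=sample, chrom=exon.chrom, pos=pos, ref=ref, alt=alt,
            gene=gene, function_class=func, zygosity=zygosity, role=role,
            emitted_by=(),
        )
        if func == "nonsynonymous":
            predictions[pv.site_key] = (
                ["deleterious"] * 3 if role == "pathogenic" else ["benign", "benign", "deleterious"]
            )
        return pv, q, pop_af

    # pathogenic archetypes: biallelic then monoallelic samples
    for i, sample in enumerate(samples[: cfg.n_biallelic]):
        genes = [g for g in panel.genes if g not in deleted_genes.get(sample, set())]
        gene = genes[int(rng.integers(len(genes)))]
        subtype = ["compound_het", "hom_truncating", "hom_missense"][
            int(rng.integers(3))
        ]
        if subtype == "compound_het":
            call_specs.append(plant(sample, gene, "het", "stopgain", "pathogenic", None))
            call_specs.append(
                plant(sample, gene, "het", "nonsynonymous", "pathogenic", None)
            )
        elif subtype == "hom_truncating":
            call_specs.append(
                plant(sample, gene, "hom", "frameshift_indel", "pathogenic", None)
            )
        else:
            call_specs.append(
                plant(sample, gene, "hom", "nonsynonymous", "pathogenic", None)
            )
    for sample in samples[cfg.n_biallelic : cfg.n_biallelic + cfg.n_monoallelic]:
        genes = [g for g in panel.genes if g not in deleted_genes.get(sample, set())]
        gene = genes[int(rng.integers(len(genes)))]
        func = ["stopgain", "frameshift_indel"][int(rng.integers(2))]
        call_specs.append(plant(sample, gene, "het", func, "pathogenic", None))

    # common polymorphisms under Hardy-Weinberg proportions
    for _ in range(cfg.n_polymorphisms):
        gene = panel.genes[int(rng.integers(len(panel.genes)))]
        exon = clean_by_gene[gene][int(rng.integers(len(clean_by_gene[gene])))]
        pos = _pick_position(rng, exon, cfg.edge_gap_length, used)
        ref, alt = _snv_alleles(rng)
        af = float(rng.uniform(*cfg.polymorphism_af_range))
        func = "synonymous" if rng.random() < 0.5 else "nonsynonymous"
        for sample in samples:
            u = rng.random()
            if u < (1 - af) ** 2:
                continue
            zyg = "hom" if u >= 1 - af**2 else "het"
            depth = max(coverage.depth_at(sample, exon, pos), 1)
            q = _true_quality(rng, zyg, depth, _pick_borderline(rng, cfg, zyg))
            pv = PlantedVariant(
                sample_id=sample, chrom=exon.chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, function_class=func, zygosity=zyg,
                role="polymorphism", emitted_by=(),
            )
            if func == "nonsynonymous" and pv.site_key not in predictions:
                predictions[pv.site_key] = ["benign", "benign", "deleterious"]
            call_specs.append((pv, q, af))

    # caller miss events, shared quality between callers
    calls_a: list[AnnotatedVariant] = []
    calls_b: list[AnnotatedVariant] = []
    for pv, q, pop_af in call_specs:
        emitted = []
        if rng.random() >= cfg.miss_prob_a:
            emitted.append(cfg.caller_a)
        if rng.random() >= cfg.miss_prob_b:
            emitted.append(cfg.caller_b)
        final = PlantedVariant(**{**asdict(pv), "emitted_by": tuple(emitted)})
        planted.append(final)
        for caller, sink in ((cfg.caller_a, calls_a), (cfg.caller_b, calls_b)):
            if caller in emitted:
                sink.append(
                    AnnotatedVariant(
                        sample_id=pv.sample_id, caller_id=caller, chrom=pv.chrom,
                        pos=pv.pos, ref=pv.ref, alt=pv.alt, gene=pv.gene,
                        region_class="exonic", function_class=pv.function_class,
                        pop_af=pop_af, quality=q,
                    )
                )

    # caller-specific artifacts on low-coverage exons
    low_cov = [e for e in panel.exons if e.cpg_island or e.repeat_adjacent]
    artifacts: list[PlantedArtifact] = []
    for caller, sink in ((cfg.caller_a, calls_a), (cfg.caller_b, calls_b)):
        for sample in samples:
            for _ in range(int(rng.poisson(cfg.artifact_rate))):
                if low_cov and rng.random() < 0.8:
                    exon = low_cov[int(rng.integers(len(low_cov)))]
                else:
                    exon = panel.exons[int(rng.integers(len(panel.exons)))]
                lo, hi = exon.start, exon.end
                pos = int(rng.integers(lo, hi)) + 1
                while (exon.chrom, pos) in used:
                    pos = int(rng.integers(lo, hi)) + 1
                used.add((exon.chrom, pos))
                ref, alt = _snv_alleles(rng)
                artifacts.append(
                    PlantedArtifact(
                        sample_id=sample, caller_id=caller, chrom=exon.chrom,
                        pos=pos, ref=ref, alt=alt,
                    )
                )
                sink.append(
                    AnnotatedVariant(
                        sample_id=sample, caller_id=caller, chrom=exon.chrom,
                        pos=pos, ref=ref, alt=alt, gene=exon.gene,
                        region_class="exonic", function_class="nonsynonymous",
                        pop_af=None, quality=_artifact_quality(rng),
                    )
                )

    manifest = GroundTruthManifest(
        samples=samples,
        true_variants=planted,
        artifacts=artifacts,
        cnvs=list(deletion_plan),
        expected_status=_expected_statuses(planted),
        predictions=predictions,
    )
    # ensure every cohort sample has an expected status
    for s in samples:
        manifest.expected_status.setdefault(s, ("undiagnosed", None))
    table_a = CohortCallTable(variants=calls_a, samples=samples, batch_id=cfg.batch_id)
    table_b = CohortCallTable(variants=calls_b, samples=samples, batch_id=cfg.batch_id)
    return table_a, table_b, manifest


@dataclass
class SyntheticCohort:
    panel: PanelDesign
    coverage: CoverageSim
    calls_a: CohortCallTable
    calls_b: CohortCallTable
    manifest: GroundTruthManifest
    deletion_plan: list[DeletionPlanEntry]
    config: SimulationConfig
    seed: int


def simulate_cohort(cfg: SimulationConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate the full synthetic study: panel, coverage, dual call sets."""
    cfg = cfg or SimulationConfig()
    panel = simulate_panel(cfg, seed)
    plan = (
        cfg.deletion_plan
        if cfg.deletion_plan is not None
        else default_deletion_plan(panel, cfg.samples)
    )
    coverage = simulate_coverage(panel, cfg, seed, plan)
    calls_a, calls_b, manifest = simulate_callsets(panel, cfg, seed, coverage, plan)
    return SyntheticCohort(
        panel=panel,
        coverage=coverage,
        calls_a=calls_a,
        calls_b=calls_b,
        manifest=manifest,
        deletion_plan=plan,
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def write_manifest(manifest: GroundTruthManifest, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest.truth_set().to_tsv(outdir / "truth.tsv")
    pd.DataFrame(
        [
            {
                "sample": pv.sample_id, "chrom": pv.chrom, "pos": pv.pos,
                "ref": pv.ref, "alt": pv.alt, "gene": pv.gene,
                "function_class": pv.function_class, "zygosity": pv.zygosity,
                "role": pv.role, "emitted_by": ",".join(pv.emitted_by),
            }
            for pv in manifest.true_variants
        ]
    ).to_csv(outdir / "planted_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample": a.sample_id, "caller": a.caller_id, "chrom": a.chrom,
                "pos": a.pos, "ref": a.ref, "alt": a.alt,
            }
            for a in manifest.artifacts
        ]
    ).to_csv(outdir / "planted_artifacts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample": c.sample_id, "gene": c.gene, "first_exon": c.first_exon,
                "last_exon": c.last_exon, "state": c.state,
            }
            for c in manifest.cnvs
        ]
    ).to_csv(outdir / "cnv_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"sample": s, "status": st, "gene": g or ""}
            for s, (st, g) in sorted(manifest.expected_status.items())
        ]
    ).to_csv(outdir / "expected_status.tsv", sep="\t", index=False)
    rows = []
    predictors = ["sift", "polyphen2", "mutation_taster"]
    for key, calls in sorted(manifest.predictions.items()):
        for name, call in zip(predictors, calls):
            rows.append(
                {
                    "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                    "predictor": name, "call": call,
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "predictor", "call"]
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "samples": manifest.samples,
                "n_true_variants": len(manifest.true_variants),
                "n_artifacts": len(manifest.artifacts),
                "n_cnvs": len(manifest.cnvs),
                "expected_status_counts": manifest.expected_status_counts(),
            },
            fh,
            sort_keys=False,
        )


def write_coverage_tracks(
    coverage: CoverageSim, panel: PanelDesign, samples: list[str], outdir: str | Path
) -> None:
    """One BedGraph-style TSV per sample, run-length encoded per exon."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        with open(outdir / f"{sample}.bedgraph", "w") as fh:
            for exon in sorted(panel.exons, key=lambda e: (e.chrom, e.start)):
                depths = coverage.depths_of(sample, exon.key)
                change = np.flatnonzero(np.diff(depths)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [depths.size]))
                for s, e in zip(starts, ends):
                    fh.write(
                        f"{exon.chrom}\t{exon.start + s}\t{exon.start + e}\t{int(depths[s])}\n"
                    )


def read_predictions_tsv(path: str | Path) -> dict[tuple, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    preds: dict[tuple, list[str]] = {}
    for r in df.itertuples(index=False):
        preds.setdefault((r.chrom, int(r.pos), r.ref, r.alt), []).append(r.call)
    return preds
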