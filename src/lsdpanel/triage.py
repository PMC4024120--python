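"""Zygosity classification, pathogenicity scoring and per-sample diagnosis.

Zygosity is read off the non-reference-allele (NRA) read fraction:
heterozygous calls sit between 30 and 50%, homozygous between 70 and
100%.  The 50-70% gap is surfaced as ``ambiguous`` (counted as one
allele downstream, with a warning) and fractions below 30% as
``low_fraction`` (real small indels can under-represent, so these are
retained and flagged rather than dropped).

Novel variants are scored against six pathogenicity criteria —
truncating/splicing class, a second mutant allele in the gene,
cosegregation, uniqueness in the cohort, rarity in the reference
population, and in-silico missense predictions — and rolled up to a
per-sample status: diagnosed (two qualifying alleles in one gene,
recessive model), carrier (exactly one), or undiagnosed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .variants import AnnotatedVariant, CohortCallTable, SiteQuality

log = logging.getLogger(__name__)

TRUNCATING_CLASSES = frozenset({"stopgain", "frameshift_indel", "splicing"})


@dataclass
class ZygosityBands:
    het: tuple[float, float] = (0.30, 0.50)
    hom: tuple[float, float] = (0.70, 1.00)


@dataclass(frozen=True)
class ZygosityCall:
    key: tuple
    nra_fraction: float
    state: str  # heterozygous | homozygous | hemizygous | ambiguous | low_fraction


def classify_zygosity(
    q: SiteQuality,
    target_is_x: bool = False,
    sample_sex: str = "unknown",
    bands: ZygosityBands | None = None,
    key: tuple = (),
) -> ZygosityCall:
    """Classify zygosity from the NRA read fraction.

    The bands partition [0, 1]: low_fraction below the het band, het,
    ambiguous between the bands, hom.  Homozygous-band calls on X-linked
    targets in declared-male samples are reported hemizygous.
    """
    bands = bands or ZygosityBands()
    f = q.nra_fraction
    if f is None:
        raise ValueError("nra_fraction missing; cannot classify zygosity")
    if f < bands.het[0]:
        state = "low_fraction"
    elif f <= bands.het[1]:
        state = "heterozygous"
    elif f < bands.hom[0]:
        state = "ambiguous"
    else:
        state = "homozygous"
        if target_is_x and sample_sex == "male":
            state = "hemizygous"
    return ZygosityCall(key=key, nra_fraction=f, state=state)


@dataclass
class FamilyGenotypes:
    """Parental carrier status per variant key: (mother, father) each in
    {present_het, present_hom, absent, unknown}."""

    entries: dict[tuple, tuple[str, str]] = field(default_factory=dict)

    def get(self, key: tuple) -> tuple[str, str]:
        return self.entries.get(key, ("unknown", "unknown"))


@dataclass(frozen=True)
class PathogenicityAssessment:
    key: tuple
    c1_truncating_or_splicing: bool
    c2_second_allele: bool
    c3_cosegregation: bool
    c4_absent_elsewhere: bool
    c5_rare: bool
    c6_missense_predicted: bool
    evaluable: frozenset[str]
    tier: str  # likely_pathogenic | uncertain | likely_benign
    review_flag: bool = False  # e.g. synonymous variant in a gene of interest

    @property
    def n_met(self) -> int:
        flags = {
            "c1": self.c1_truncating_or_splicing,
            "c2": self.c2_second_allele,
            "c3": self.c3_cosegregation,
            "c4": self.c4_absent_elsewhere,
            "c5": self.c5_rare,
            "c6": self.c6_missense_predicted,
        }
        return sum(flags[c] for c in self.evaluable)


def _tier(n_met: int, c1: bool, c6: bool) -> str:
    if n_met >= 4 and (c1 or c6):
        return "likely_pathogenic"
    if n_met >= 2:
        return "uncertain"
    return "likely_benign"


def assess_pathogenicity(
    v: AnnotatedVariant,
    same_gene_variants: list[AnnotatedVariant],
    cohort: CohortCallTable,
    family: FamilyGenotypes | None = None,
    predictions: dict[tuple, list[str]] | None = None,
    zygosity: ZygosityCall | None = None,
) -> PathogenicityAssessment:
    """Score one variant against the six pathogenicity criteria.

    c1  truncating class (stopgain / frameshift / splicing)
    c2  second mutant allele in the gene: another surviving variant in
        the same gene and sample, or a homozygous/hemizygous state
    c3  cosegregation: parental genotypes consistent with transmission
        (evaluable only when both parents are typed)
    c4  absent elsewhere: this sample is the only cohort carrier
    c5  reference-population frequency missing (novel) or < 0.01
    c6  missense with a majority of available in-silico predictors
        calling it deleterious (evaluable only for missense with >= 1
        prediction)

    The tier rule is a package convention (the per-criterion flags are
    always emitted so users can re-weight): likely_pathogenic needs >= 4
    evaluable criteria met including c1 or c6; 2-3 met is uncertain;
    <= 1 likely_benign.
    """
    evaluable = {"c1", "c2", "c4", "c5"}
    c1 = v.function_class in TRUNCATING_CLASSES

    others = [
        o
        for o in same_gene_variants
        if o.sample_id == v.sample_id and o.site_key != v.site_key
    ]
    biallelic_state = zygosity is not None and zygosity.state in (
        "homozygous",
        "hemizygous",
    )
    c2 = bool(others) or biallelic_state

    c3 = False
    if family is not None:
        mother, father = family.get(v.sample_key)
        if mother != "unknown" and father != "unknown":
            evaluable.add("c3")
            parent_carries = [s in ("present_het", "present_hom") for s in (mother, father)]
            if biallelic_state:
                c3 = all(parent_carries)
            else:
                c3 = any(parent_carries)

    c4 = len(cohort.carriers(v.site_key)) == 1
    c5 = v.pop_af is None or v.pop_af < 0.01

    c6 = False
    preds = (predictions or {}).get(v.site_key, [])
    if v.function_class == "nonsynonymous" and preds:
        evaluable.add("c6")
        deleterious = sum(p == "deleterious" for p in preds)
        c6 = deleterious > len(preds) - deleterious

    flags = {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5, "c6": c6}
    n_met = sum(flags[c] for c in evaluable)
    return PathogenicityAssessment(
        key=v.sample_key,
        c1_truncating_or_splicing=c1,
        c2_second_allele=c2,
        c3_cosegregation=c3,
        c4_absent_elsewhere=c4,
        c5_rare=c5,
        c6_missense_predicted=c6,
        evaluable=frozenset(evaluable),
        tier=_tier(n_met, c1, c6),
        review_flag=v.function_class == "synonymous",
    )


@dataclass(frozen=True)
class DiagnosisRecord:
    sample_id: str
    status: str  # diagnosed | carrier | undiagnosed
    gene: str | None
    supporting: tuple[tuple, ...] = ()
    review_keys: tuple[tuple, ...] = ()  # synonymous variants in the best gene


def _qualifying(a: PathogenicityAssessment) -> bool:
    return a.tier == "likely_pathogenic" or (
        a.tier == "uncertain" and a.c1_truncating_or_splicing
    )


def diagnose_sample(
    sample_id: str,
    variants: list[tuple[AnnotatedVariant, PathogenicityAssessment, ZygosityCall]],
    inheritance: dict[str, str] | None = None,
    family: FamilyGenotypes | None = None,
) -> DiagnosisRecord:
    """Roll a sample's assessed variants up to a diagnostic status.

    Qualifying alleles per gene: a likely_pathogenic variant, or an
    uncertain one with a truncating class.  A homozygous call counts as
    two alleles under autosomal-recessive inheritance, a hemizygous call
    as two under X-linked.  Two heterozygous qualifying variants are
    counted biallelic (phase unknown) unless parental genotypes prove a
    cis configuration, which demotes the gene to one allele.
    """
    inheritance = inheritance or {}
    per_gene: dict[str, list] = {}
    for v, a, z in variants:
        if v.gene is None or not _qualifying(a):
            continue
        per_gene.setdefault(v.gene, []).append((v, a, z))

    best_gene, best_alleles, best_entries = None, 0, []
    for gene in sorted(per_gene):
        entries = per_gene[gene]
        model = inheritance.get(gene, "AR")
        alleles = 0
        het_entries = []
        for v, a, z in entries:
            if z.state == "homozygous" and model == "AR":
                alleles += 2
            elif z.state == "hemizygous" and model == "XL":
                alleles += 2
            else:
                if z.state in ("ambiguous", "low_fraction"):
                    log.warning(
                        "sample %s %s: zygosity %s counted as one allele",
                        sample_id,
                        v.site_key,
                        z.state,
                    )
                alleles += 1
                het_entries.append(v)
        if alleles >= 2 and len(het_entries) == 2 and family is not None:
            if _proven_cis(het_entries[0], het_entries[1], family):
                alleles = 1
        if alleles > best_alleles:
            best_gene, best_alleles, best_entries = gene, alleles, entries

    if best_alleles >= 2:
        status = "diagnosed"
    elif best_alleles == 1:
        status = "carrier"
    else:
        status = "undiagnosed"
    review = tuple(
        v.sample_key
        for v, a, z in variants
        if a.review_flag and v.gene == best_gene and best_gene is not None
    )
    return DiagnosisRecord(
        sample_id=sample_id,
        status=status,
        gene=best_gene,
        supporting=tuple(v.sample_key for v, _, _ in best_entries),
        review_keys=review,
    )


def _proven_cis(
    v1: AnnotatedVariant, v2: AnnotatedVariant, family: FamilyGenotypes
) -> bool:
    """Both variants demonstrably inherited from the same single parent."""
    g1, g2 = family.get(v1.sample_key), family.get(v2.sample_key)
    if "unknown" in g1 or "unknown" in g2:
        return False
    from_mother = (g1[0].startswith("present"), g2[0].startswith("present"))
    from_father = (g1[1].startswith("present"), g2[1].startswith("present"))
    both_maternal = all(from_mother) and not any(from_father)
    both_paternal = all(from_father) and not any(from_mother)
    return both_maternal or both_paternal


def diagnoses_to_frame(records: list[DiagnosisRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample": r.sample_id,
            "status": r.status,
            "gene": r.gene or "",
            "n_supporting": len(r.supporting),
            "supporting": ";".join(
                f"{k[1]}:{k[2]}:{k[3]}>{k[4]}" for k in r.supporting
            ),
        }
        for r in sorted(records, key=lambda r: r.sample_id)
    ]
    return pd.DataFrame(
        rows, columns=["sample", "status", "gene", "n_supporting", "supporting"]
    )
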