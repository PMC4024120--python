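"""Panel design: the exon targets of a diagnostic capture panel.

A panel is a set of genes, each decomposed into exon targets (plus
exon-intron boundaries) that the capture baits enrich.  Intervals are
stored 0-based half-open, the BED convention; conversion to the 1-based
variant coordinate system happens only in the variant I/O layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class ExonTarget:
    """One captured exon (or exon plus boundary) of a panel gene.

    ``cpg_island`` and ``repeat_adjacent`` mark exons whose local sequence
    architecture is known to depress hybridization-capture coverage:
    CpG-island exons can drop to zero depth, and baits cannot be designed
    inside repeats so repeat-adjacent exons carry uncovered margins.
    """

    gene: str
    exon_id: int  # ordinal within the gene, 1-based
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    cpg_island: bool = False
    repeat_adjacent: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"exon interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.exon_id < 1:
            raise PanelError(f"exon_id must be >= 1, got {self.exon_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene, self.exon_id)


@dataclass
class PanelDesign:
    """A capture panel: gene roster plus merged, sorted exon targets."""

    genes: list[str]
    exons: list[ExonTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.genes)
        for exon in self.exons:
            if exon.gene not in known:
                raise PanelError(f"exon references unlisted gene {exon.gene!r}")

    @property
    def total_target_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_of(self, gene: str) -> list[ExonTarget]:
        return sorted(
            (e for e in self.exons if e.gene == gene), key=lambda e: e.exon_id
        )

    def exon(self, gene: str, exon_id: int) -> ExonTarget:
        for e in self.exons:
            if e.gene == gene and e.exon_id == exon_id:
                return e
        raise KeyError(f"no exon {exon_id} in gene {gene}")


_NAME_RE = re.compile(r"^(?P<gene>[A-Za-z0-9.\-]+)_exon(?P<num>\d+)$")


def _parse_flags(token: str) -> tuple[bool, bool]:
    if token in (".", ""):
        return False, False
    flags = set(token.split(","))
    unknown = flags - {"cpg_island", "repeat_adjacent"}
    if unknown:
        raise PanelError(f"unknown exon flags: {sorted(unknown)}")
    return "cpg_island" in flags, "repeat_adjacent" in flags


def read_panel_bed(path: str | Path) -> PanelDesign:
    """Read a panel definition from BED (0-based half-open).

    Required columns: chrom, start, end, name (``GENE_exonN``).  An
    optional 5th column carries comma-separated exon flags
    (``cpg_island``, ``repeat_adjacent``) or ``.``.  Overlapping
    intervals of the same gene are merged; exon ordinals are then
    reassigned by genomic order within each gene.
    """
    raw: list[ExonTarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(
                    f"{path}: line {lineno}: expected >=4 tab-separated columns"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise PanelError(
                    f"{path}: line {lineno}: end <= start ({start}, {end})"
                )
            m = _NAME_RE.match(name)
            if m is None:
                raise PanelError(
                    f"{path}: line {lineno}: name {name!r} not of form GENE_exonN"
                )
            cpg, repeat = _parse_flags(fields[4]) if len(fields) >= 5 else (False, False)
            raw.append(
                ExonTarget(
                    gene=m["gene"],
                    exon_id=int(m["num"]),
                    chrom=chrom,
                    start=start,
                    end=end,
                    cpg_island=cpg,
                    repeat_adjacent=repeat,
                )
            )
    if not raw:
        raise PanelError(f"{path}: no target intervals")
    return _build_panel(raw)


def _build_panel(raw: list[ExonTarget]) -> PanelDesign:
    """Merge overlapping same-gene intervals and renumber exon ordinals."""
    genes: list[str] = []
    exons: list[ExonTarget] = []
    for exon in raw:
        if exon.gene not in genes:
            genes.append(exon.gene)
    for gene in genes:
        per_gene = sorted(
            (e for e in raw if e.gene == gene), key=lambda e: (e.chrom, e.start)
        )
        merged: list[ExonTarget] = []
        for exon in per_gene:
            if (
                merged
                and exon.chrom == merged[-1].chrom
                and exon.start <= merged[-1].end
            ):
                prev = merged[-1]
                merged[-1] = replace(
                    prev,
                    end=max(prev.end, exon.end),
                    cpg_island=prev.cpg_island or exon.cpg_island,
                    repeat_adjacent=prev.repeat_adjacent or exon.repeat_adjacent,
                )
            else:
                merged.append(exon)
        exons.extend(
            replace(e, exon_id=i) for i, e in enumerate(merged, start=1)
        )
    return PanelDesign(genes=genes, exons=exons)


def write_panel_bed(panel: PanelDesign, path: str | Path) -> None:
    """Write the panel as BED with the flags column used by read_panel_bed."""
    with open(path, "w") as fh:
        for e in sorted(panel.exons, key=lambda e: (e.chrom, e.start)):
            flags = ",".join(
                name
                for name, on in (
                    ("cpg_island", e.cpg_island),
                    ("repeat_adjacent", e.repeat_adjacent),
                )
                if on
            ) or "."
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.gene}_exon{e.exon_id}\t{flags}\n"
            )
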