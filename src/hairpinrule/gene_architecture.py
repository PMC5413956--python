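"""Coding/intergenic partition, architecture statistics and metagene profiles.

"Coding" is strand-agnostic: a position is coding when it lies inside at
least one annotated gene on either strand, so the genome splits into a
two-way partition whose site counts always sum to the total. Gene
footprints include the stop codon; mean protein length therefore subtracts
one codon from the mean gene length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GeneModel, GenomeRecord
from .hairpin_scan import PalindromeSite


@dataclass(frozen=True)
class CodingMask:
    """Per-position boolean coding indicator (True = inside >= 1 gene)."""

    mask: np.ndarray
    L: int

    @property
    def coding_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class ArchitectureStats:
    n_genes: int
    coding_fraction: float
    mean_intergenic_len: float
    mean_protein_len: float


@dataclass
class MetageneProfile:
    """Per-offset site counts around start or stop codons, deconvoluted by
    the orientation of the neighboring gene (upstream gene for start
    anchors, downstream gene for stop anchors)."""

    anchor: str
    window: int
    offsets: np.ndarray
    counts: dict[str, np.ndarray]
    n_genes_per_stratum: dict[str, int]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def build_coding_mask(genome: GenomeRecord, genes: list[GeneModel]) -> CodingMask:
    """Union of gene footprints on either strand; wrap-aware on circles."""
    L = genome.length
    mask = np.zeros(L, dtype=bool)
    for g in genes:
        if g.end > g.start:
            if g.end > L:
                raise ValueError(f"gene {g.gene_id!r} exceeds genome bounds")
            mask[g.start : g.end] = True
        else:
            if not genome.circular:
                raise ValueError(
                    f"gene {g.gene_id!r} wraps the origin of a linear genome"
                )
            mask[g.start :] = True
            mask[: g.end] = True
    return CodingMask(mask=mask, L=L)


def _intergenic_runs(mask: np.ndarray, circular: bool) -> list[int]:
    """Lengths of maximal non-coding runs; on a circle the run through the
    origin is a single run."""
    L = len(mask)
    if mask.all():
        return []
    if not mask.any():
        return [L]
    noncoding = ~mask
    # boundaries of runs in linear frame
    diff = np.diff(noncoding.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if noncoding[0]:
        starts = [0] + starts
    if noncoding[-1]:
        ends = ends + [L]
    runs = [e - s for s, e in zip(starts, ends)]
    if circular and noncoding[0] and noncoding[-1] and len(runs) > 1:
        runs[0] += runs.pop()  # merge the run through the origin
    return runs


def architecture_stats(
    genome: GenomeRecord, genes: list[GeneModel]
) -> ArchitectureStats:
    """Coding fraction, mean intergenic run length, mean protein length."""
    if not genes:
        raise ValueError("no genes")
    cm = build_coding_mask(genome, genes)
    runs = _intergenic_runs(cm.mask, genome.circular)
    mean_gene_nt = float(np.mean([g.length(genome.length) for g in genes]))
    return ArchitectureStats(
        n_genes=len(genes),
        coding_fraction=cm.coding_fraction,
        mean_intergenic_len=float(np.mean(runs)) if runs else 0.0,
        mean_protein_len=mean_gene_nt / 3.0 - 1.0,
    )


def classify_sites(
    sites: list[PalindromeSite], mask: CodingMask
) -> tuple[int, int]:
    """(n_coding, n_intergenic) by each site's center coordinate."""
    n_coding = sum(1 for s in sites if mask.mask[s.center])
    return n_coding, len(sites) - n_coding


def _anchor_pos(gene: GeneModel, anchor: str, L: int) -> int:
    """Genomic position of the first nt of the start codon or last nt of
    the stop codon, strand-aware."""
    last = (gene.end - 1) % L
    if anchor == "start":
        return gene.start if gene.strand == "+" else last
    return last if gene.strand == "+" else gene.start


def _nearest_gene(
    genes: list[GeneModel], idx: int, pos: int, direction: int, L: int, circular: bool
) -> GeneModel | None:
    """Nearest other gene in the given genomic direction (+1 right, -1
    left), measured boundary-to-anchor; circular search when allowed."""
    best_d = None
    best_g = None
    for j, g in enumerate(genes):
        if j == idx:
            continue
        if direction > 0:
            d = (g.start - pos) % L
        else:
            d = (pos - ((g.end - 1) % L)) % L
        if d == 0:
            d = L
        if not circular:
            # reject neighbors only reachable through the origin
            if direction > 0 and g.start < pos:
                continue
            if direction < 0 and ((g.end - 1) % L) > pos:
                continue
        if best_d is None or d < best_d:
            best_d = d
            best_g = g
    return best_g


def metagene_profile(
    sites: list[PalindromeSite],
    genes: list[GeneModel],
    genome: GenomeRecord,
    anchor: str = "stop",
    window: int = 300,
) -> MetageneProfile:
    """Count site centers at signed offsets from each gene's anchor.

    Offsets are in the gene's reading direction (+1 is always downstream);
    each (gene, site) pair within the window counts once. The stratum is
    the orientation of the neighboring gene relative to the anchored gene:
    the upstream gene for start anchors, the downstream gene for stop
    anchors ("same" = same strand). Genes without a neighbor on the
    relevant side (possible only on linear genomes) are skipped.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    if window < 1:
        raise ValueError("window must be >= 1")
    if not genes:
        raise ValueError("no genes")
    L = genome.length
    offsets = np.arange(-window, window + 1)
    counts = {
        "same_orientation": np.zeros(2 * window + 1, dtype=np.int64),
        "opposite_orientation": np.zeros(2 * window + 1, dtype=np.int64),
    }
    n_genes_per_stratum = {"same_orientation": 0, "opposite_orientation": 0}
    centers = [s.center for s in sites]
    for idx, gene in enumerate(genes):
        apos = _anchor_pos(gene, anchor, L)
        # neighbor side in genomic coordinates depends on the strand
        if anchor == "start":
            direction = -1 if gene.strand == "+" else +1  # upstream gene
        else:
            direction = +1 if gene.strand == "+" else -1  # downstream gene
        neighbor = _nearest_gene(genes, idx, apos, direction, L, genome.circular)
        if neighbor is None:
            continue
        stratum = (
            "same_orientation"
            if neighbor.strand == gene.strand
            else "opposite_orientation"
        )
        n_genes_per_stratum[stratum] += 1
        for c in centers:
            if genome.circular:
                delta = (c - apos) % L
                if delta > L // 2:
                    delta -= L
            else:
                delta = c - apos
            if gene.strand == "-":
                delta = -delta
            if -window <= delta <= window:
                counts[stratum][delta + window] += 1
    return MetageneProfile(
        anchor=anchor,
        window=window,
        offsets=offsets,
        counts=counts,
        n_genes_per_stratum=n_genes_per_stratum,
    )
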