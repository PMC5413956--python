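"""Synthetic genomes and proteome tables with known ground truth.

The genome generator emulates the architecture of a gene-dense circular
virus: non-overlapping genes on both strands reaching a target coding
fraction near 0.90, short intergenic gaps, and stem-loop palindromes
planted at a controllable intergenic:coding ratio. The background
sequence is rejection-sampled so that, under the scan parameters the
genome is generated for, the only detectable stem-loop sites are the
planted ones — planted-site recall and false-positive assertions in tests
are therefore exact, not probabilistic.

The proteome generator emulates two virion tables whose shared ortholog
abundances are log-normally distributed and rho-correlated on the log
scale, with per-replicate multiplicative noise and a controllable number
of proteins detected in only one virion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomeRecord
from .hairpin_scan import PalindromeSite, ScanParams, scan_palindromes

_BASES = np.array([0, 1, 2, 3], dtype=np.int8)  # A C G T
_DECODE = np.array(list("ACGTN"))


@dataclass(frozen=True)
class GenomeSimSpec:
    """Study-condition defaults: a 50 kb slice of a ~376 kb genome that is
    90% coding with ~88 nt mean intergenic gaps, GC 0.43, and a planted
    palindrome density matching ~226 sites per 376 kb of which ~2/3 are
    intergenic."""

    L: int = 50_000
    n_genes: int = 57
    target_coding_fraction: float = 0.90
    strand_prob: float = 0.5
    n_palindromes: int = 30
    p_intergenic: float = 0.668
    stem_len: int = 10
    loop_len: Optional[int] = None  # None: uniform over the scan loop range
    offset_mode: str = "uniform"  # or "after_stop"
    offset_mean: float = 25.0
    gc: float = 0.43
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_intergenic <= 1.0:
            raise ValueError("p_intergenic must be in [0, 1]")
        if self.offset_mode not in ("uniform", "after_stop"):
            raise ValueError(f"unknown offset_mode {self.offset_mode!r}")
        if self.n_genes < 1 or self.L < 100:
            raise ValueError("need n_genes >= 1 and L >= 100")


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Study-condition defaults: 114 shared viral + 52 shared host ortholog
    pairs, 117/30 proteins detected only in A/B, log-normal abundances
    spanning several orders of magnitude, true log-scale rho 0.93."""

    n_shared_viral: int = 114
    n_shared_host: int = 52
    n_only_a: int = 117
    n_only_b: int = 30
    log_abundance_sd: float = 1.5
    noise_sd: float = 0.2
    true_rho: float = 0.93
    frac_low_peptides: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.true_rho) > 1.0:
            raise ValueError("|true_rho| must be <= 1")
        if min(self.n_shared_viral, self.n_shared_host, self.n_only_a, self.n_only_b) < 0:
            raise ValueError("counts must be >= 0")


def _partition(rng, total: int, n: int, minimum: int, multiple: int = 1) -> np.ndarray:
    """Randomly split ``total`` into n parts, each >= minimum and a
    multiple of ``multiple``; total must itself allow it."""
    if total < n * minimum:
        raise ValueError("infeasible partition")
    units = (total - n * minimum) // multiple
    w = rng.dirichlet(np.full(n, 5.0))
    alloc = np.floor(w * units).astype(int)
    leftover = units - alloc.sum()
    for i in rng.choice(n, size=int(leftover), replace=True):
        alloc[i] += 1
    parts = minimum + alloc * multiple
    # absorb any remainder not expressible in multiples into the last part
    parts[-1] += total - parts.sum()
    return parts


class _Allocator:
    """Tracks free sub-intervals and carves site allocations out of them."""

    def __init__(self, intervals: list[tuple[int, int]]):
        self.free = [iv for iv in intervals if iv[1] > iv[0]]

    def capacity(self, size: int) -> int:
        return sum(max(0, e - s - size + 1) for s, e in self.free)

    def place(self, rng, size: int, at: Optional[int] = None) -> Optional[int]:
        """Allocate ``size`` nt; uniform over feasible offsets, or at the
        requested start when it fits. Returns the start or None."""
        if at is not None:
            for i, (s, e) in enumerate(self.free):
                if s <= at and at + size <= e:
                    self._carve(i, at, size)
                    return at
            return None
        weights = np.array([max(0, e - s - size + 1) for s, e in self.free], dtype=float)
        if weights.sum() == 0:
            return None
        i = int(rng.choice(len(self.free), p=weights / weights.sum()))
        s, e = self.free[i]
        start = int(rng.integers(s, e - size + 1))
        self._carve(i, start, size)
        return start

    def _carve(self, i: int, start: int, size: int) -> None:
        s, e = self.free.pop(i)
        if start > s:
            self.free.append((s, start))
        if start + size < e:
            self.free.append((start + size, e))


def _plan_placements(rng, intervals, sizes):
    """Lay out non-overlapping allocations of the given sizes inside the
    free intervals.

    Two stages: each size is reserved in an interval chosen with
    probability proportional to its remaining room, then the sites of
    each interval are placed in random order with uniformly drawn
    spacings. Reservation avoids the fragmentation loss of sequential
    random placement, so layout succeeds whenever the per-interval
    capacities allow it. Returns starts aligned with ``sizes``, or None
    when infeasible.
    """
    if not sizes:
        return []
    rem = np.array([e - s for s, e in intervals], dtype=float)
    assigned: list[list[int]] = [[] for _ in intervals]
    order = sorted(range(len(sizes)), key=lambda j: -sizes[j])
    for j in order:
        size = sizes[j]
        w = np.maximum(rem - size + 1, 0.0)
        if w.sum() <= 0:
            return None
        i = int(rng.choice(len(intervals), p=w / w.sum()))
        assigned[i].append(j)
        rem[i] -= size
    starts = [0] * len(sizes)
    for i, (s, e) in enumerate(intervals):
        idxs = assigned[i]
        if not idxs:
            continue
        rng.shuffle(idxs)
        slack = (e - s) - sum(sizes[j] for j in idxs)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(idxs)))
        pos, prev = s, 0
        for k, j in enumerate(idxs):
            pos += int(cuts[k]) - prev
            prev = int(cuts[k])
            starts[j] = pos
            pos += sizes[j]
    return starts


def _draw_background(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _write_site(rng, codes: np.ndarray, start: int, stem: int, loop: int, gc: float) -> None:
    """Write arm + loop + revcomp(arm) at ``start`` (allocation includes a
    1 nt guard on each side whose bases are forced not to pair)."""
    arm = _draw_background(rng, stem, gc)
    loop_seq = _draw_background(rng, loop, gc)
    site = start + 1  # skip the left guard
    codes[site : site + stem] = arm
    codes[site + stem : site + stem + loop] = loop_seq
    codes[site + stem + loop : site + 2 * stem + loop] = 3 - arm[::-1]
    # guards: left guard base must not pair with right guard base
    x = int(rng.integers(0, 4))
    y_choices = [b for b in range(4) if b + x != 3]
    codes[start] = x
    codes[start + 2 * stem + loop + 1] = y_choices[int(rng.integers(0, 3))]


def simulate_genome(
    spec: GenomeSimSpec, params: Optional[ScanParams] = None
) -> tuple[GenomeRecord, list[GeneModel], list[PalindromeSite]]:
    """Simulate a circular annotated genome with planted stem-loops.

    Returns (genome, genes, truth). Under ``params`` (default ScanParams)
    the scanner recovers exactly the planted sites: their centers are the
    only detectable loop midpoints. The whole construction, including the
    random rotation that may put a gene or site across the origin, is
    deterministic given ``spec.seed``.
    """
    if params is None:
        params = ScanParams()
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    total_coding = round(spec.target_coding_fraction * L)
    total_coding -= total_coding % 3  # keep gene lengths in whole codons
    gene_lens = _partition(rng, total_coding, spec.n_genes, minimum=60, multiple=3)
    gap_lens = _partition(rng, L - total_coding, spec.n_genes, minimum=2)
    genes: list[GeneModel] = []
    gene_ivs: list[tuple[int, int]] = []
    gap_ivs: list[tuple[int, int]] = []
    pos = 0
    for i in range(spec.n_genes):
        start, end = pos, pos + int(gene_lens[i])
        strand = "+" if rng.random() < spec.strand_prob else "-"
        genes.append(GeneModel(f"gene_{i + 1:04d}", start, end, strand))
        gene_ivs.append((start, end))
        gap_ivs.append((end, end + int(gap_lens[i])))
        pos = end + int(gap_lens[i])
    assert pos == L

    loop_for = lambda: (
        spec.loop_len
        if spec.loop_len is not None
        else int(rng.integers(params.loop_min, params.loop_max + 1))
    )
    intergenic_flags = rng.random(spec.n_palindromes) < spec.p_intergenic
    sizes = []  # (stem, loop, alloc size incl. 1 nt guards)
    for _ in range(spec.n_palindromes):
        stem, loop = spec.stem_len, loop_for()
        sizes.append((stem, loop, 2 * stem + loop + 2))
    coding_sizes = [sz for sz, flag in zip(sizes, intergenic_flags) if not flag]
    inter_sizes = [sz for sz, flag in zip(sizes, intergenic_flags) if flag]

    plan: list[tuple[int, int, int]] = []  # (alloc_start, stem, loop)
    if spec.offset_mode == "after_stop" and inter_sizes:
        # anchor intergenic sites at exponential offsets downstream of stops
        inter_alloc = _Allocator(gap_ivs)
        stop_of = {g.gene_id: (g.end - 1 if g.strand == "+" else g.start) for g in genes}
        for stem, loop, size in inter_sizes:
            start = None
            for _ in range(200):
                g = genes[int(rng.integers(len(genes)))]
                d = int(rng.exponential(spec.offset_mean))
                if g.strand == "+":
                    want = stop_of[g.gene_id] + 1 + d
                else:
                    want = stop_of[g.gene_id] - 1 - d - size + 1
                start = inter_alloc.place(rng, size, at=want)
                if start is not None:
                    break
            if start is None:
                start = inter_alloc.place(rng, size)
            if start is None:
                raise ValueError(
                    "infeasible simulation: cannot fit all planted sites; "
                    "reduce n_palindromes or enlarge the genome"
                )
            plan.append((start, stem, loop))
    else:
        inter_starts = _plan_placements(rng, gap_ivs, [s[2] for s in inter_sizes])
        if inter_starts is None:
            raise ValueError(
                "infeasible simulation: intergenic space cannot fit the "
                "planted sites; reduce n_palindromes or enlarge the genome"
            )
        plan.extend(
            (start, stem, loop)
            for start, (stem, loop, _) in zip(inter_starts, inter_sizes)
        )
    coding_starts = _plan_placements(rng, gene_ivs, [s[2] for s in coding_sizes])
    if coding_starts is None:
        raise ValueError(
            "infeasible simulation: coding space cannot fit the planted "
            "sites; reduce n_palindromes or enlarge the genome"
        )
    plan.extend(
        (start, stem, loop)
        for start, (stem, loop, _) in zip(coding_starts, coding_sizes)
    )

    codes = _draw_background(rng, L, spec.gc)
    protected = np.zeros(L, dtype=bool)
    for start, stem, loop in plan:
        _write_site(rng, codes, start, stem, loop, spec.gc)
        protected[start : start + 2 * stem + loop + 2] = True
    truth_centers = {
        (start + 1 + stem + (loop - 1) // 2): (start, stem, loop)
        for start, stem, loop in plan
    }

    # rejection: redraw background wherever an unintended site appears
    for _ in range(80):
        record = GenomeRecord("sim", "".join(_DECODE[codes]), circular=True)
        detected = scan_palindromes(record, params)
        bad = [s for s in detected if s.center not in truth_centers]
        missing = set(truth_centers) - {s.center for s in detected}
        if not bad and not missing:
            break
        for s in bad:
            span = np.arange(s.left_arm_start - 1, s.left_arm_start + s.footprint + 1) % L
            editable = span[~protected[span]]
            if len(editable):
                codes[editable] = _draw_background(rng, len(editable), spec.gc)
            if protected[span].any():
                # partly induced by planted content: rewrite the planted
                # site(s) it touches (they remain valid planted sites)
                touched = set(span[protected[span]])
                for start, stem, loop in plan:
                    if touched & set(range(start, start + 2 * stem + loop + 2)):
                        _write_site(rng, codes, start, stem, loop, spec.gc)
        for c in missing:  # pragma: no cover - defensive
            start, stem, loop = truth_centers[c]
            _write_site(rng, codes, start, stem, loop, spec.gc)
    else:  # pragma: no cover
        raise RuntimeError("rejection sampling did not converge")

    # random rotation so genes/sites may span the origin
    rot = int(rng.integers(L))
    codes = np.roll(codes, rot)

    def shift_iv(start: int, end: int) -> tuple[int, int]:
        s = (start + rot) % L
        e = (end - 1 + rot) % L + 1
        return s, e

    genes = [
        GeneModel(g.gene_id, *shift_iv(g.start, g.end), g.strand) for g in genes
    ]
    genes.sort(key=lambda g: g.start)
    truth = []
    for i, (start, stem, loop) in enumerate(sorted(plan)):
        left = (start + 1 + rot) % L
        center = (start + 1 + stem + (loop - 1) // 2 + rot) % L
        end = (left + 2 * stem + loop - 1) % L + 1
        truth.append(
            PalindromeSite(
                site_id=f"truth_{i + 1:04d}",
                left_arm_start=left,
                stem_len=stem,
                loop_len=loop,
                mismatches=0,
                center=center,
                span=(left, end if end != left else L),
            )
        )
    genome = GenomeRecord("sim", "".join(_DECODE[codes]), circular=True)
    return genome, genes, truth


def simulate_proteomes(
    spec: ProteomeSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]], dict]:
    """Simulate two virion proteome tables plus their ortholog map.

    Shared proteins get log-normal base abundances; virion B's log
    abundance is a rho-correlated Gaussian copy; each replicate column
    multiplies the base intensity by log-normal noise. Proteins detected
    in only one virion have no ortholog partner. All intended-detected
    entries carry >= 2 peptides; ``frac_low_peptides`` adds extra entries
    with a single peptide to exercise the filter.
    """
    rng = np.random.default_rng(spec.seed)
    sd, rho = spec.log_abundance_sd, spec.true_rho

    def correlated(n):
        z_a = rng.normal(0.0, sd, n)
        z_b = rho * z_a + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0.0, sd, n)
        return z_a, z_b

    zv_a, zv_b = correlated(spec.n_shared_viral)
    zh_a, zh_b = correlated(spec.n_shared_host)
    rows_a, rows_b, pairs = [], [], []

    def intensities(z):
        base = 1e8 * np.exp(z)
        return (
            base * np.exp(rng.normal(0.0, spec.noise_sd)),
            base * np.exp(rng.normal(0.0, spec.noise_sd)),
        )

    def entry(pid, source, z):
        i1, i2 = intensities(z)
        return {
            "protein_id": pid,
            "source": source,
            "peptide_count": int(2 + rng.poisson(8)),
            "ibaq_rep1": i1,
            "ibaq_rep2": i2,
        }

    for i in range(spec.n_shared_viral):
        id_a, id_b = f"NV_{i + 1:04d}", f"MV_{i + 1:04d}"
        rows_a.append(entry(id_a, "viral", zv_a[i]))
        rows_b.append(entry(id_b, "viral", zv_b[i]))
        pairs.append((id_a, id_b))
    for i in range(spec.n_shared_host):
        id_a, id_b = f"HA_{i + 1:04d}", f"HB_{i + 1:04d}"
        rows_a.append(entry(id_a, "host", zh_a[i]))
        rows_b.append(entry(id_b, "host", zh_b[i]))
        pairs.append((id_a, id_b))
    # bystanders detected in a single virion, biased toward low abundance
    for i in range(spec.n_only_a):
        rows_a.append(entry(f"ONLYA_{i + 1:04d}", "host", rng.normal(-sd, sd)))
    for i in range(spec.n_only_b):
        rows_b.append(entry(f"ONLYB_{i + 1:04d}", "host", rng.normal(-sd, sd)))
    for rows, tag in ((rows_a, "A"), (rows_b, "B")):
        n_low = round(spec.frac_low_peptides * len(rows))
        for i in range(n_low):
            e = entry(f"LOW{tag}_{i + 1:04d}", "host", rng.normal(-sd, sd))
            e["peptide_count"] = 1
            rows.append(e)
    table_a, table_b = pd.DataFrame(rows_a), pd.DataFrame(rows_b)
    truth = {
        "true_rho": rho,
        "log_a_viral": zv_a,
        "log_b_viral": zv_b,
        "log_a_host": zh_a,
        "log_b_host": zh_b,
    }
    return table_a, table_b, pairs, truth
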