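"""Genome-wide stem-loop (palindrome) detection.

A site is a left arm of ``stem_len`` nt that pairs, in reverse-complement
register, with the immediately following right arm across a short loop:

    5'-[left arm]-[loop]-[right arm]-3'      left ~= revcomp(right)

Up to ``max_mismatches`` substitutions are tolerated between the left arm
and the reverse complement of the right arm; bulges are not modelled, and
N never pairs. On circular replicons candidate windows wrap across the
origin. The scanner enumerates every loop placement ``(a, l)`` (loop
occupying ``[a, a+l)``) and extends the stem outward pair by pair; among
overlapping candidates sharing a loop midpoint only the one with maximal
stem length (then fewest mismatches, then smallest loop, then smallest
left-arm start) is kept, so one physical hairpin is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome_io import GenomeRecord, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScanParams:
    """Stem-loop descriptor limits.

    The defaults (stem >= 10 bp, loop 3-8 nt, at most one mismatch) define
    a strong, terminator-like hairpin; they are configurable because any
    published palindrome total depends on the descriptor used.
    """

    min_stem: int = 10
    loop_min: int = 3
    loop_max: int = 8
    max_mismatches: int = 1
    circular: Optional[bool] = None  # None: honor the genome's flag

    def __post_init__(self) -> None:
        if self.min_stem < 2:
            raise ValueError("min_stem must be >= 2")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.max_mismatches >= self.min_stem:
            raise ValueError("max_mismatches must be < min_stem")


@dataclass(frozen=True)
class PalindromeSite:
    """One detected stem-loop; ``center`` is the loop midpoint (left-rounded
    for even loops) and is the single coordinate used in all downstream
    coding/intergenic classification."""

    site_id: str
    left_arm_start: int
    stem_len: int
    loop_len: int
    mismatches: int
    center: int
    span: tuple[int, int]  # [start, end) footprint; end <= start encodes wrap

    @property
    def score(self) -> int:
        return self.stem_len - self.mismatches

    @property
    def footprint(self) -> int:
        return 2 * self.stem_len + self.loop_len


_LUT = np.full(128, -1, dtype=np.int8)
for _c, _v in _CODE.items():
    _LUT[ord(_c)] = _v


def encode(seq: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4 as an int8 array (A+T == C+G == 3)."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_core(codes, L, loop_min, loop_max, min_stem, max_mm, circular):
    """Enumerate per-(loop start, loop length) maximal candidates.

    Fills a preallocated (n, 4) int64 array with rows (a, l, stem, mm) and
    returns (array, row count). Pure Python; replaced by a JIT-compiled
    twin at import time when numba is available.
    """
    cap = L * (loop_max - loop_min + 1)
    out = np.empty((cap, 4), dtype=np.int64)
    n_out = 0
    for l in range(loop_min, loop_max + 1):
        for a in range(L):
            # innermost pair is (a-1, a+l)
            if not circular and (a - 1 < 0 or a + l >= L):
                continue
            mm = 0
            best_stem = 0
            best_mm = 0
            k = 0
            while True:
                p = a - 1 - k
                q = a + l + k
                if circular:
                    if 2 * (k + 1) + l > L:
                        break
                    p %= L
                    q %= L
                elif p < 0 or q >= L:
                    break
                x = codes[p]
                y = codes[q]
                if x == 4 or y == 4 or x + y != 3:
                    mm += 1
                    if mm > max_mm:
                        break
                best_stem = k + 1
                best_mm = mm
                k += 1
            if best_stem >= min_stem:
                out[n_out, 0] = a
                out[n_out, 1] = l
                out[n_out, 2] = best_stem
                out[n_out, 3] = best_mm
                n_out += 1
    return out, n_out


_scan_core_fast = None
try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _scan_core_fast = njit(cache=False)(_scan_core)
except Exception:  # pragma: no cover
    _scan_core_fast = None


def scan_palindromes(
    genome: GenomeRecord, params: Optional[ScanParams] = None
) -> list[PalindromeSite]:
    """Detect all maximal stem-loop sites in a genome.

    Deterministic; output sorted by left-arm start. Honors the genome's
    circular flag unless overridden through ``params.circular``.
    """
    if params is None:
        params = ScanParams()
    L = genome.length
    if L <= 2 * params.min_stem + params.loop_min:
        raise ValueError("genome shorter than the minimal site footprint")
    codes = encode(genome.seq)
    circ = genome.circular if params.circular is None else params.circular
    core = _scan_core_fast if _scan_core_fast is not None else _scan_core
    raw, n_raw = core(
        codes,
        L,
        params.loop_min,
        params.loop_max,
        params.min_stem,
        params.max_mismatches,
        circ,
    )
    # maximality: one site per loop midpoint
    best: dict[int, tuple] = {}
    for a, l, stem, mm in (tuple(int(v) for v in row) for row in raw[:n_raw]):
        center = (a + (l - 1) // 2) % L
        left = (a - stem) % L if circ else a - stem
        key = (-stem, mm, l, left)
        if center not in best or key < best[center][0]:
            best[center] = (key, a, l, stem, mm)
    sites = []
    for center, (_, a, l, stem, mm) in best.items():
        left = (a - stem) % L if circ else a - stem
        end = a + l + stem
        if circ:
            end %= L
        sites.append((left, stem, l, mm, center, end))
    sites.sort(key=lambda t: (t[0], t[2]))
    return [
        PalindromeSite(
            site_id=f"pal_{i + 1:05d}",
            left_arm_start=left,
            stem_len=stem,
            loop_len=l,
            mismatches=mm,
            center=center,
            span=(left, end),
        )
        for i, (left, stem, l, mm, center, end) in enumerate(sites)
    ]


def is_perfect_palindrome(seq: str) -> bool:
    """True iff seq has even length and equals its reverse complement."""
    if not seq:
        raise ValueError("empty sequence")
    return len(seq) % 2 == 0 and seq == revcomp(seq)


# ---------------------------------------------------------------------------
# single-hairpin folding (base-pair maximization, no energy model)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class HairpinFold:
    """A single contiguous stem-loop fold of a short sequence.

    ``pairs`` are nested, non-crossing Watson-Crick (i, j) index pairs from
    the outside in; the loop is the unpaired stretch enclosed by the
    innermost pair (the whole sequence when no pair forms).
    """

    seq: str
    pairs: tuple[tuple[int, int], ...]
    cleavage_offset: Optional[int] = None

    @property
    def stem_len(self) -> int:
        return len(self.pairs)

    @property
    def loop_span(self) -> tuple[int, int]:
        """Half-open index range of the loop."""
        if not self.pairs:
            return (0, len(self.seq))
        i_in, j_in = self.pairs[-1]
        return (i_in + 1, j_in)

    @property
    def loop_seq(self) -> str:
        a, b = self.loop_span
        return self.seq[a:b]


def fold_hairpin(seq: str, min_loop: int = 3) -> HairpinFold:
    """Fold a sequence into its best single stem-loop.

    Exhausts every outer pair placement (i0, j0) and extends a contiguous
    Watson-Crick stem inward subject to a loop of at least ``min_loop``
    unpaired nt. Maximizes the number of pairs; ties prefer the smaller
    left index, then the larger right index (shortest dangling 3' tail).
    """
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {min_loop + 2}")
    best_pairs: tuple = ()
    best_key = (0, 0, 0)
    for i0 in range(n):
        for j0 in range(n - 1, i0 + min_loop, -1):
            pairs = []
            k = 0
            while True:
                i, j = i0 + k, j0 - k
                if j - i - 1 < min_loop:
                    break
                if (seq[i], seq[j]) not in _WC:
                    break
                pairs.append((i, j))
                k += 1
            key = (len(pairs), -i0, j0)
            if key > best_key:
                best_key = key
                best_pairs = tuple(pairs)
    return HairpinFold(seq=seq, pairs=best_pairs)


def place_cleavage(fold: HairpinFold, cleavage_pos: int) -> str:
    """Classify an observed mRNA cleavage/poly(A) position on the fold.

    Returns 'in_loop', 'in_stem' or 'outside'.
    """
    n = len(fold.seq)
    if not (0 <= cleavage_pos < n):
        raise ValueError(f"cleavage position {cleavage_pos} outside [0, {n})")
    paired = {i for ij in fold.pairs for i in ij}
    if cleavage_pos in paired:
        return "in_stem"
    a, b = fold.loop_span
    if a <= cleavage_pos < b:
        return "in_loop"
    return "outside"
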