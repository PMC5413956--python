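"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the scanner: string slicing against
the raw definition, explicit enumeration for the Fisher test.
"""

from fractions import Fraction
from math import comb


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mismatches(left, right):
    """Mismatch count between a left arm and revcomp(right arm); N never
    counts as a match."""
    rc = _revcomp(right)
    return sum(1 for x, y in zip(left, rc) if x == "N" or y == "N" or x != y)


def brute_force_scan(seq, min_stem, loop_min, loop_max, max_mismatches, circular):
    """Test every (loop start, loop length, stem length) triple directly
    against the site definition, then keep one site per loop midpoint
    (max stem, then fewest mismatches, then smallest loop, then smallest
    left-arm start). Returns sorted (left, stem, loop, mm, center) tuples."""
    L = len(seq)
    best = {}
    for l in range(loop_min, loop_max + 1):
        for a in range(L):
            for s in range(min_stem, L):
                if circular:
                    if 2 * s + l > L:
                        break
                    left = "".join(seq[(a - s + i) % L] for i in range(s))
                    right = "".join(seq[(a + l + i) % L] for i in range(s))
                else:
                    if a - s < 0 or a + l + s > L:
                        break
                    left, right = seq[a - s : a], seq[a + l : a + l + s]
                mm = _mismatches(left, right)
                if mm > max_mismatches:
                    break  # mismatches only grow with the stem
                center = (a + (l - 1) // 2) % L
                start = (a - s) % L if circular else a - s
                key = (-s, mm, l, start)
                if center not in best or key < best[center][0]:
                    best[center] = (key, start, s, l, mm)
    return sorted(
        (start, s, l, mm, center)
        for center, (_, start, s, l, mm) in best.items()
    )


def fisher_two_sided_exact(a, b, c, d):
    """Exact two-sided Fisher p as a Fraction, by full enumeration of all
    tables with the observed margins (probability-at-most-observed rule)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    r2 = c + d
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return total
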