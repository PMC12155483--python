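"""Independent brute-force reference implementations of the WSH scores.

Written by direct enumeration over windows / epialleles / read pairs, with
no code shared with the package, so they can serve as oracles.  Reads are
given as (offset, states) segments relative to the block or region start.
"""

from __future__ import annotations

import itertools
import math


def covers(seg: tuple[int, str], start: int, stop: int) -> bool:
    off, states = seg
    return off <= start and stop <= off + len(states)


def states_at(seg: tuple[int, str], idx: int) -> str | None:
    off, states = seg
    if off <= idx < off + len(states):
        return states[idx - off]
    return None


def oracle_mhl(segments: list[tuple[int, str]], width: int) -> float:
    """Enumerate every (start, length) window and every read explicitly."""
    num = 0.0
    den = 0.0
    for length in range(1, width + 1):
        observed = 0
        all_m = 0
        for start in range(0, width - length + 1):
            for seg in segments:
                if covers(seg, start, start + length):
                    observed += 1
                    if all(states_at(seg, i) == "M" for i in range(start, start + length)):
                        all_m += 1
        if observed:
            num += length * (all_m / observed)
            den += length
    return math.nan if den == 0 else num / den


def oracle_pdr(segments: list[tuple[int, str]], min_cpgs_per_read: int = 4) -> float:
    classified = [s for _, s in segments if len(s) >= min_cpgs_per_read]
    if not classified:
        return math.nan
    discordant = sum(1 for s in classified if len(set(s)) > 1)
    return discordant / len(classified)


def _epialleles(segments: list[tuple[int, str]], width: int = 4) -> list[str]:
    return [s for off, s in segments if off == 0 and len(s) == width]


def oracle_pm(segments: list[tuple[int, str]], width: int = 4) -> float:
    alleles = _epialleles(segments, width)
    if not alleles:
        return math.nan
    n = len(alleles)
    return 1.0 - sum((alleles.count(a) / n) ** 2 for a in set(alleles))


def oracle_me(segments: list[tuple[int, str]], width: int = 4) -> float:
    alleles = _epialleles(segments, width)
    if not alleles:
        return math.nan
    n = len(alleles)
    ent = 0.0
    for a in set(alleles):
        p = alleles.count(a) / n
        ent -= p * math.log2(p)
    return ent / width


def _pair_shared(a, b, positions, focal_idx, window):
    shared = []
    for idx, pos in enumerate(positions):
        if abs(pos - positions[focal_idx]) > window:
            continue
        sa, sb = states_at(a, idx), states_at(b, idx)
        if sa is not None and sb is not None:
            shared.append((sa, sb))
    return shared


def oracle_fdrp(
    segments, positions, focal_idx, window=50, min_overlap_cpgs=1
) -> float:
    """All-pairs enumeration (no sampling)."""
    cand = [s for s in segments if states_at(s, focal_idx) is not None]
    evaluated = discordant = 0
    for a, b in itertools.combinations(cand, 2):
        shared = _pair_shared(a, b, positions, focal_idx, window)
        if len(shared) < min_overlap_cpgs:
            continue
        evaluated += 1
        if any(x != y for x, y in shared):
            discordant += 1
    return math.nan if evaluated == 0 else discordant / evaluated


def oracle_qfdrp(
    segments, positions, focal_idx, window=50, min_overlap_cpgs=1
) -> float:
    cand = [s for s in segments if states_at(s, focal_idx) is not None]
    vals = []
    for a, b in itertools.combinations(cand, 2):
        shared = _pair_shared(a, b, positions, focal_idx, window)
        if len(shared) < min_overlap_cpgs:
            continue
        vals.append(sum(1 for x, y in shared if x != y) / len(shared))
    return math.nan if not vals else sum(vals) / len(vals)
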