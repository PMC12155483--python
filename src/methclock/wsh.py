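"""Within-sample heterogeneity (WSH) scores from read-level CpG patterns.

Six scores are implemented, following the conventions of the read-level
heterogeneity literature:

* **MHL** (methylation haplotype load) — length-weighted fraction of fully
  methylated substrings among all observed substrings of a CpG block.
* **PDR** (proportion of discordant reads) — fraction of reads carrying
  both methylated and unmethylated calls, among reads covering at least
  ``min_cpgs_per_read`` CpGs.
* **PM** (epipolymorphism) — 1 minus the sum of squared epiallele
  frequencies over the 16 patterns of a 4-CpG block.
* **ME** (methylation entropy) — Shannon entropy (bits) of the same 16
  epiallele frequencies, normalized by 4 so that the uniform distribution
  scores 1.
* **FDRP** (fraction of discordant read pairs) — per CpG: the fraction of
  read pairs that disagree at any CpG both reads observe within ±``window``
  bp of the focal CpG.
* **qFDRP** — quantitative variant: mean over pairs of the Hamming distance
  divided by the number of shared CpGs.

MHL and PDR are evaluated on the full CpG run of each target region; PM and
ME on sliding windows of exactly four consecutive CpGs; FDRP and qFDRP per
CpG.  Scores with insufficient read support are missing (NaN), never zero:
zero is a meaningful value for every one of these metrics.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PatternSet, ReadPattern, TargetRegion

METRICS = ("MHL", "PDR", "PM", "ME", "FDRP", "qFDRP")
_CANON = {m.upper(): m for m in METRICS}

#: Block width for epipolymorphism / methylation entropy.
PM_ME_BLOCK_WIDTH = 4


@dataclass(frozen=True)
class CpGBlock:
    """A half-open interval of CpG indices within one region."""

    region_id: str
    start: int
    stop: int
    block_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError("block must be a non-empty [start, stop) index interval")
        if not self.block_id:
            object.__setattr__(self, "block_id", f"{self.region_id}[{self.start}:{self.stop}]")

    @property
    def width(self) -> int:
        return self.stop - self.start


def block_segments(reads: Sequence[ReadPattern], block: CpGBlock) -> list[tuple[int, str]]:
    """Restrict reads to a block: (offset within block, states) per read.

    Patterns are contiguous, so each read yields at most one segment.
    """
    segs: list[tuple[int, str]] = []
    for rp in reads:
        lo = max(rp.first_cpg_index, block.start)
        hi = min(rp.first_cpg_index + len(rp.states), block.stop)
        if hi > lo:
            segs.append((lo - block.start, rp.states[lo - rp.first_cpg_index : hi - rp.first_cpg_index]))
    return segs


def _canonical(reads: Sequence[ReadPattern]) -> list[ReadPattern]:
    return sorted(reads, key=lambda rp: (rp.first_cpg_index, rp.states))


# ---------------------------------------------------------------------------
# Block-level scores


def pdr(
    reads: Sequence[ReadPattern],
    block: CpGBlock,
    min_cpgs_per_read: int = 4,
    min_reads: int = 10,
) -> tuple[float, int]:
    """Proportion of discordant reads in a block; returns (score, support).

    A read is classified only if it observes at least ``min_cpgs_per_read``
    of the block's CpGs; it is concordant iff all its observed states are
    identical.  Support is the number of classified reads.
    """
    classified = 0
    discordant = 0
    for _, states in block_segments(reads, block):
        if len(states) < min_cpgs_per_read:
            continue
        classified += 1
        if "M" in states and "U" in states:
            discordant += 1
    if classified < min_reads:
        return math.nan, classified
    return discordant / classified, classified


def mhl(
    reads: Sequence[ReadPattern],
    block: CpGBlock,
    min_reads: int = 10,
) -> tuple[float, int]:
    """Methylation haplotype load of a block; returns (score, support).

    For each substring length ``i`` (1..block width), MH_i is the fraction of
    observed length-``i`` substrings (windows fully covered by one read) that
    are fully methylated; MHL = sum(i * MH_i) / sum(i) over lengths with at
    least one observed substring.  Support is the number of overlapping reads.
    """
    L = block.width
    observed = np.zeros(L + 1, dtype=np.int64)  # index = substring length
    all_m = np.zeros(L + 1, dtype=np.int64)
    segs = block_segments(reads, block)
    for _, states in segs:
        c = len(states)
        lengths = np.arange(1, c + 1)
        observed[1 : c + 1] += c - lengths + 1
        # all-M substrings of length i inside an M-run of length r: r - i + 1
        for run in states.split("U"):
            r = len(run)
            if r:
                li = np.arange(1, r + 1)
                all_m[1 : r + 1] += r - li + 1
    support = len(segs)
    if support < min_reads or not observed[1:].any():
        return math.nan, support
    lengths = np.arange(1, L + 1)
    mask = observed[1:] > 0
    weights = lengths[mask]
    mh = all_m[1:][mask] / observed[1:][mask]
    return float(np.dot(weights, mh) / weights.sum()), support


def _epiallele_freqs(
    reads: Sequence[ReadPattern], block: CpGBlock
) -> tuple[dict[str, int], int]:
    if block.width != PM_ME_BLOCK_WIDTH:
        raise ValueError(f"PM/ME blocks must span exactly {PM_ME_BLOCK_WIDTH} CpGs")
    counts: dict[str, int] = {}
    n = 0
    for off, states in block_segments(reads, block):
        if off == 0 and len(states) == block.width:
            counts[states] = counts.get(states, 0) + 1
            n += 1
    return counts, n


def epipolymorphism(
    reads: Sequence[ReadPattern], block: CpGBlock, min_reads: int = 10
) -> tuple[float, int]:
    """Epipolymorphism of a 4-CpG block: 1 - sum of squared epiallele freqs."""
    counts, n = _epiallele_freqs(reads, block)
    if n < min_reads:
        return math.nan, n
    return 1.0 - sum((c / n) ** 2 for c in counts.values()), n


def methylation_entropy(
    reads: Sequence[ReadPattern], block: CpGBlock, min_reads: int = 10
) -> tuple[float, int]:
    """Normalized Shannon entropy of the 16 epiallele frequencies (0·log0 = 0)."""
    counts, n = _epiallele_freqs(reads, block)
    if n < min_reads:
        return math.nan, n
    ent = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return ent / PM_ME_BLOCK_WIDTH, n


# ---------------------------------------------------------------------------
# Per-CpG pairwise scores


def _pairs_for_cpg(
    reads: Sequence[ReadPattern],
    region: TargetRegion,
    cpg_index: int,
    window: int,
    max_pairs: int,
    rng: np.random.Generator | None,
) -> tuple[list[tuple[ReadPattern, ReadPattern]], int]:
    """Candidate read pairs at a focal CpG, sampled down to ``max_pairs``."""
    cand = _canonical([rp for rp in reads if rp.state_at(cpg_index) is not None])
    n = len(cand)
    total = n * (n - 1) // 2
    if total <= max_pairs:
        pairs = [(cand[i], cand[j]) for i in range(n) for j in range(i + 1, n)]
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        ks = rng.choice(total, size=max_pairs, replace=False)
        pairs = []
        for k in sorted(int(k) for k in ks):
            # decode linear pair index k -> (i, j), i < j
            i = int(n - 2 - math.floor(math.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2 - 0.5))
            j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
            pairs.append((cand[i], cand[j]))
    return pairs, n


def _shared_states(
    a: ReadPattern, b: ReadPattern, region: TargetRegion, cpg_index: int, window: int
) -> list[tuple[str, str]]:
    focal_pos = region.cpg_positions[cpg_index]
    lo = max(a.first_cpg_index, b.first_cpg_index)
    hi = min(a.first_cpg_index + len(a.states), b.first_cpg_index + len(b.states))
    out = []
    for i in range(lo, hi):
        if abs(region.cpg_positions[i] - focal_pos) <= window:
            out.append((a.state_at(i), b.state_at(i)))
    return out


def fdrp(
    reads: Sequence[ReadPattern],
    region: TargetRegion,
    cpg_index: int,
    window: int = 50,
    max_pairs: int = 40,
    min_overlap_cpgs: int = 1,
    min_reads: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Fraction of discordant read pairs at one CpG; returns (score, support).

    A pair is discordant iff the two reads differ at any CpG they both
    observe within ±``window`` bp of the focal CpG.  When the number of
    pairs exceeds ``max_pairs``, that many pairs are sampled without
    replacement using ``rng``.  Support is the number of candidate reads.
    """
    pairs, n = _pairs_for_cpg(reads, region, cpg_index, window, max_pairs, rng)
    if n < min_reads:
        return math.nan, n
    evaluated = 0
    discordant = 0
    for a, b in pairs:
        shared = _shared_states(a, b, region, cpg_index, window)
        if len(shared) < min_overlap_cpgs:
            continue
        evaluated += 1
        if any(x != y for x, y in shared):
            discordant += 1
    if evaluated == 0:
        return math.nan, n
    return discordant / evaluated, n


def qfdrp(
    reads: Sequence[ReadPattern],
    region: TargetRegion,
    cpg_index: int,
    window: int = 50,
    max_pairs: int = 40,
    min_overlap_cpgs: int = 1,
    min_reads: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Quantitative FDRP: mean normalized Hamming distance over read pairs."""
    pairs, n = _pairs_for_cpg(reads, region, cpg_index, window, max_pairs, rng)
    if n < min_reads:
        return math.nan, n
    values = []
    for a, b in pairs:
        shared = _shared_states(a, b, region, cpg_index, window)
        if len(shared) < min_overlap_cpgs:
            continue
        mismatches = sum(1 for x, y in shared if x != y)
        values.append(mismatches / len(shared))
    if not values:
        return math.nan, n
    return float(np.mean(values)), n


# ---------------------------------------------------------------------------
# Score matrices


@dataclass
class ScoreMatrix:
    """Samples x features WSH score matrix with per-entry read support."""

    metric: str
    values: pd.DataFrame
    support: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        import json

        with open(path, "w") as fh:
            fh.write(f"# metric={self.metric} params={json.dumps(self.params, sort_keys=True)}\n")
            self.values.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        import json

        with open(path) as fh:
            header = fh.readline().strip()
            values = pd.read_csv(fh, sep="\t", index_col=0)
        metric, params = "", {}
        if header.startswith("# metric="):
            body = header[len("# metric=") :]
            metric, _, rest = body.partition(" params=")
            params = json.loads(rest) if rest else {}
        support = values.notna().astype(int)
        return cls(metric, values, support, params)


def region_blocks(region: TargetRegion, metric: str) -> list[CpGBlock]:
    """Feature blocks of a region for a block-level metric.

    MHL and PDR use the full consecutive-CpG run of the region (amplicons
    are short); PM and ME use sliding windows of exactly 4 CpGs.
    """
    metric = canonical_metric(metric)
    n = region.n_cpgs
    if metric in ("MHL", "PDR"):
        if n == 0:
            return []
        return [CpGBlock(region.region_id, 0, n, block_id=region.region_id)]
    if metric in ("PM", "ME"):
        w = PM_ME_BLOCK_WIDTH
        return [
            CpGBlock(
                region.region_id,
                i,
                i + w,
                block_id=f"{region.region_id}:{region.cpg_positions[i]}-{region.cpg_positions[i + w - 1]}",
            )
            for i in range(n - w + 1)
        ]
    raise ValueError(f"{metric} is not a block-level metric")


def canonical_metric(metric: str) -> str:
    key = metric.upper()
    if key not in _CANON:
        raise ValueError(f"unknown metric {metric!r}; valid: {', '.join(METRICS)}")
    return _CANON[key]


def _cpg_rng(seed: int, sample_id: str, feature_id: str) -> np.random.Generator:
    # stable per-(sample, CpG) stream so results do not depend on iteration order
    return np.random.default_rng([seed, zlib.crc32(f"{sample_id}|{feature_id}".encode())])


def compute_score_matrix(
    ps: PatternSet,
    metric: str,
    seed: int = 0,
    unit: str = "block",
    **params,
) -> ScoreMatrix:
    """Compute one WSH metric for every sample and feature of a PatternSet.

    FDRP/qFDRP produce one column per CpG; MHL/PDR one per region; PM/ME one
    per 4-CpG sliding window.  ``unit="cpg"`` broadcasts block-level values
    to each member CpG (useful when mixing with per-CpG features).
    ``params`` are forwarded to the metric (min_reads, window, ...).
    """
    metric = canonical_metric(metric)
    samples = ps.sample_ids
    columns: list[str] = []
    cells: list = []  # (region, evaluator) per column

    if metric in ("FDRP", "qFDRP"):
        fn = fdrp if metric == "FDRP" else qfdrp
        for region in ps.regions:
            for i, cid in enumerate(region.cpg_ids()):
                columns.append(cid)
                cells.append((region.region_id, i, fn))
        values = np.full((len(samples), len(columns)), np.nan)
        support = np.zeros((len(samples), len(columns)), dtype=np.int64)
        for si, sample in enumerate(samples):
            for ci, (region_id, cpg_index, fn) in enumerate(cells):
                reads = ps.reads_for(sample, region_id)
                rng = _cpg_rng(seed, sample, columns[ci])
                values[si, ci], support[si, ci] = fn(
                    reads, ps.region(region_id), cpg_index, rng=rng, **params
                )
        vdf = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=columns)
        sdf = pd.DataFrame(support, index=vdf.index, columns=columns)
        return ScoreMatrix(metric, vdf, sdf, dict(params, seed=seed, unit="cpg"))

    block_fn = {"MHL": mhl, "PDR": pdr, "PM": epipolymorphism, "ME": methylation_entropy}[metric]
    blocks: list[CpGBlock] = []
    for region in ps.regions:
        blocks.extend(region_blocks(region, metric))
    columns = [b.block_id for b in blocks]
    values = np.full((len(samples), len(blocks)), np.nan)
    support = np.zeros((len(samples), len(blocks)), dtype=np.int64)
    for si, sample in enumerate(samples):
        for ci, block in enumerate(blocks):
            reads = ps.reads_for(sample, block.region_id)
            values[si, ci], support[si, ci] = block_fn(reads, block, **params)
    vdf = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=columns)
    sdf = pd.DataFrame(support, index=vdf.index, columns=columns)
    if unit == "cpg":
        vdf, sdf = _broadcast_to_cpgs(ps, blocks, vdf, sdf)
    elif unit != "block":
        raise ValueError("unit must be 'block' or 'cpg'")
    return ScoreMatrix(metric, vdf, sdf, dict(params, seed=seed, unit=unit))


def _broadcast_to_cpgs(ps, blocks, vdf, sdf):
    """Assign each CpG the value of the block containing it (mean if several)."""
    cols: dict[str, list[int]] = {}
    for ci, block in enumerate(blocks):
        region = ps.region(block.region_id)
        for i in range(block.start, block.stop):
            cols.setdefault(f"{block.region_id}:{region.cpg_positions[i]}", []).append(ci)
    new_v = pd.DataFrame(
        {cid: vdf.iloc[:, idxs].mean(axis=1) for cid, idxs in cols.items()}, index=vdf.index
    )
    new_s = pd.DataFrame(
        {cid: sdf.iloc[:, idxs].max(axis=1) for cid, idxs in cols.items()}, index=sdf.index
    )
    return new_v, new_s
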