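"""Read-level targeted BS-seq cohort simulator with known ground truth.

The generator emulates a small amplicon panel sequenced over a cohort of
serially passaged cell cultures from donors of different ages.  Each CpG
belongs to one of four signal classes:

* ``mean_drift`` — the methylation probability shifts linearly with
  culture passage (the classic clock CpG);
* ``age_drift`` — it shifts linearly with donor chronological age (the
  confounder a passage clock must exclude);
* ``disorder`` — CpGs grouped into blocks whose reads come from an
  ordered/disordered epiallele mixture: with probability
  pi(passage) = pi0 + gamma * passage a read is a random epiallele
  (i.i.d. Bernoulli(0.5) states), otherwise it is fully methylated with
  probability p0 or fully unmethylated.  With p0 = 0.5 the expected mean
  methylation is constant in passage while pattern-level heterogeneity
  scores (PDR, PM, ME, MHL) drift — the signal channel that only
  read-level data can see;
* ``null`` — constant probability.

On top of binomial read sampling, every (sample, CpG) probability receives
a small Gaussian jitter (``sample_noise_sd``, on the probability scale) to
emulate biological and technical between-sample variation; all
probabilities are clamped to ``clamp`` (default [0.02, 0.98], mimicking
incomplete bisulfite conversion and measurement floors).  Reads cover
contiguous CpG runs with uniformly random starts, emulating short
paired-end amplicon coverage at the CpG level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import PatternSet, ReadPattern, SampleRecord, TargetRegion

CLASSES = ("mean_drift", "age_drift", "disorder", "null")


@dataclass(frozen=True)
class RegionPlan:
    """Layout of one simulated amplicon.

    ``classes``, ``slopes`` and ``baselines`` are per-CpG; contiguous runs
    of class ``disorder`` form blocks whose mixture parameters are taken
    from ``baselines`` (ordered fully-M probability p0) and ``slopes``
    (disorder-probability slope gamma per passage), with ``disorder_pi0``
    the baseline disorder probability.
    """

    region_id: str
    chrom: str
    start: int
    cpg_spacing: int
    classes: tuple[str, ...]
    slopes: tuple[float, ...]
    baselines: tuple[float, ...]
    disorder_pi0: float = 0.05

    def __post_init__(self) -> None:
        n = len(self.classes)
        if not (len(self.slopes) == len(self.baselines) == n) or n == 0:
            raise ValueError("classes, slopes, baselines must be equal-length and non-empty")
        for c in self.classes:
            if c not in CLASSES:
                raise ValueError(f"unknown CpG class {c!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.classes)

    def positions(self) -> tuple[int, ...]:
        return tuple(self.start + i * self.cpg_spacing for i in range(self.n_cpgs))

    def to_region(self) -> TargetRegion:
        pos = self.positions()
        return TargetRegion(self.region_id, self.chrom, self.start, pos[-1] + 2, pos)

    def disorder_blocks(self) -> list[tuple[int, int]]:
        blocks, run = [], None
        for i, c in enumerate(self.classes + ("null",)):
            if c == "disorder":
                run = i if run is None else run
            elif run is not None:
                blocks.append((run, i))
                run = None
        return blocks


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cohort; validated before generation."""

    regions: tuple[RegionPlan, ...]
    n_samples: int = 44
    passage_range: tuple[int, int] = (1, 12)
    age_range: tuple[float, float] = (20.0, 70.0)
    depth: float = 1000.0  # Poisson mean reads per (sample, region)
    read_len_range: tuple[int, int] = (5, 10)  # CpGs covered per read
    sample_noise_sd: float = 0.03
    clamp: tuple[float, float] = (0.02, 0.98)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.clamp
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("clamp bounds must satisfy 0 <= lo < hi <= 1")
        if self.n_samples < 2 or self.depth <= 0:
            raise ValueError("need n_samples >= 2 and positive depth")
        if self.read_len_range[0] < 1 or self.read_len_range[0] > self.read_len_range[1]:
            raise ValueError("invalid read_len_range")
        p_lo, p_hi = self.passage_range
        a_lo, a_hi = self.age_range
        if p_lo < 0 or p_lo > p_hi or a_lo < 0 or a_lo > a_hi:
            raise ValueError("invalid passage or age range")
        for rp in self.regions:
            for cls, slope, p0 in zip(rp.classes, rp.slopes, rp.baselines):
                if cls == "disorder":
                    ends = (rp.disorder_pi0 + slope * p_lo, rp.disorder_pi0 + slope * p_hi)
                elif cls == "mean_drift":
                    ends = (p0 + slope * p_lo, p0 + slope * p_hi)
                elif cls == "age_drift":
                    ends = (p0 + slope * a_lo, p0 + slope * a_hi)
                else:
                    ends = (p0, p0)
                # slopes must keep noiseless trajectories inside the clamp
                # band, so clamping only ever trims noise tails
                if min(ends) < lo - 1e-9 or max(ends) > hi + 1e-9:
                    raise ValueError(
                        f"{rp.region_id}: class {cls} trajectory {ends} leaves clamp band {self.clamp}"
                    )

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for rp in self.regions:
            pos = rp.positions()
            block_of = {}
            for b0, b1 in rp.disorder_blocks():
                for i in range(b0, b1):
                    block_of[i] = f"{rp.region_id}[{b0}:{b1}]"
            for i, (cls, slope, p0) in enumerate(zip(rp.classes, rp.slopes, rp.baselines)):
                rows.append(
                    {
                        "cpg_id": f"{rp.region_id}:{pos[i]}",
                        "region_id": rp.region_id,
                        "cpg_index": i,
                        "position": pos[i],
                        "class": cls,
                        "slope": slope,
                        "baseline": p0,
                        "block_id": block_of.get(i, ""),
                    }
                )
        return pd.DataFrame(rows).set_index("cpg_id")


def _clamp(x, lo, hi):
    return np.clip(x, lo, hi)


def simulate_cohort(cfg: SimConfig) -> tuple[PatternSet, list[SampleRecord], pd.DataFrame]:
    """Generate a cohort: read patterns, sample sheet and per-CpG truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p_lo, p_hi = cfg.passage_range
    n_passages = p_hi - p_lo + 1
    passages = np.array([p_lo + i % n_passages for i in range(cfg.n_samples)])
    ages = np.round(rng.uniform(*cfg.age_range, size=cfg.n_samples), 1)
    samples = [
        SampleRecord(f"S{i + 1:03d}", int(passages[i]), float(ages[i]), "synthetic")
        for i in range(cfg.n_samples)
    ]

    regions = [rp.to_region() for rp in cfg.regions]
    ps = PatternSet(regions)
    lo, hi = cfg.clamp
    for rp in cfg.regions:
        n_cpgs = rp.n_cpgs
        classes = np.asarray(rp.classes)
        slopes = np.asarray(rp.slopes)
        baselines = np.asarray(rp.baselines)
        blocks = rp.disorder_blocks()
        in_block = np.zeros(n_cpgs, dtype=bool)
        for b0, b1 in blocks:
            in_block[b0:b1] = True
        for rec in samples:
            # per-sample methylation probabilities for independent CpGs
            t_pass, t_age = rec.passage, rec.donor_age
            p = baselines.copy()
            p[classes == "mean_drift"] += slopes[classes == "mean_drift"] * t_pass
            p[classes == "age_drift"] += slopes[classes == "age_drift"] * t_age
            p = _clamp(p + rng.normal(0.0, cfg.sample_noise_sd, size=n_cpgs), lo, hi)

            n_reads = int(rng.poisson(cfg.depth))
            if n_reads == 0:
                continue
            lens = rng.integers(
                cfg.read_len_range[0], cfg.read_len_range[1] + 1, size=n_reads
            )
            lens = np.minimum(lens, n_cpgs)
            starts = rng.integers(0, n_cpgs - lens + 1)

            states = rng.random((n_reads, n_cpgs)) < p  # independent-CpG channel
            for b0, b1 in blocks:
                pi0 = rp.disorder_pi0
                gamma = float(slopes[b0])  # block-wide disorder slope
                p0_block = float(baselines[b0])
                pi = float(
                    _clamp(pi0 + gamma * t_pass + rng.normal(0.0, cfg.sample_noise_sd), 0.0, 1.0)
                )
                disordered = rng.random(n_reads) < pi
                ordered_m = rng.random(n_reads) < _clamp(
                    p0_block + rng.normal(0.0, cfg.sample_noise_sd), lo, hi
                )
                width = b1 - b0
                block_states = np.where(
                    disordered[:, None],
                    rng.random((n_reads, width)) < 0.5,
                    ordered_m[:, None],
                )
                states[:, b0:b1] = block_states

            letters = np.where(states, "M", "U")
            for r in range(n_reads):
                s, L = int(starts[r]), int(lens[r])
                ps.add(
                    ReadPattern(rec.sample_id, rp.region_id, s, "".join(letters[r, s : s + L]))
                )
    return ps, samples, cfg.truth_table()


# ---------------------------------------------------------------------------
# Stock configurations


def _region(region_id, chrom, start, entries, spacing=10, pi0=0.05) -> RegionPlan:
    classes, slopes, baselines = zip(*entries)
    return RegionPlan(region_id, chrom, start, spacing, classes, slopes, baselines, pi0)


def default_benchmark_config(seed: int = 20260301) -> SimConfig:
    """The stock 44-sample benchmark cohort: 4 regions, 60 CpGs.

    Mirrors a small targeted panel: 24 passage-informative CpGs
    (mean drift ±0.02/passage from baselines 0.25/0.74), two 5-CpG
    disorder blocks (pi0 = 0.05, gamma = 0.045/passage, p0 = 0.5),
    7 donor-age-confounded CpGs (0.004/year) and 19 null CpGs.  Depth
    1000 reads per region per sample.  CpGs are spaced 10 bp apart so
    every region satisfies the 5-CpGs-in-150-bp eligibility rule.
    """
    up = ("mean_drift", 0.02, 0.25)
    down = ("mean_drift", -0.02, 0.74)
    # most real CpGs sit near fully unmethylated or fully methylated
    null_lo = ("null", 0.0, 0.12)
    null_hi = ("null", 0.0, 0.88)
    age = ("age_drift", 0.004, 0.15)
    dis = ("disorder", 0.045, 0.5)
    r1 = _region("R1", "chrSim", 1_000, [up, down, up, null_lo, up, down, up, up, null_hi, down, up, up, down, null_lo, up])
    r2 = _region("R2", "chrSim", 5_000, [down, up, null_hi, up, down, up, down, null_lo, up, up, down, up, null_hi, down, up])
    r3 = _region("R3", "chrSim", 9_000, [dis] * 5 + [age] * 7 + [null_lo, null_hi, null_lo])
    r4 = _region("R4", "chrSim", 13_000, [dis] * 5 + [null_lo, null_hi] * 5)
    return SimConfig(regions=(r1, r2, r3, r4), seed=seed)


def mixed_signal_config(seed: int = 0, n_samples: int = 36, depth: float = 500.0) -> SimConfig:
    """A cohort whose signal is half mean-drift, half disorder-only.

    One region carries 5 mean-drift CpGs (among nulls); two regions are
    pure 5-CpG disorder blocks whose mean methylation is pinned at 0.5.
    Effect sizes match :func:`default_benchmark_config`, so each channel
    alone is informative but noisy — the regime where combining mean
    methylation with heterogeneity scores should pay off.
    """
    up = ("mean_drift", 0.02, 0.25)
    down = ("mean_drift", -0.02, 0.74)
    null_lo = ("null", 0.0, 0.12)
    null_hi = ("null", 0.0, 0.88)
    dis = ("disorder", 0.045, 0.5)
    r1 = _region("M1", "chrSim", 1_000, [up, null_lo, down, null_hi, up, null_lo, down, null_hi, up, null_lo])
    r2 = _region("D1", "chrSim", 5_000, [dis] * 5, pi0=0.05)
    r3 = _region("D2", "chrSim", 9_000, [dis] * 5, pi0=0.08)
    return SimConfig(regions=(r1, r2, r3), n_samples=n_samples, depth=depth, seed=seed)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
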