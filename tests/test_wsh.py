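"""Heterogeneity scores against exhaustive brute-force oracles and their limits."""

import math

import numpy as np
import pytest
from scipy import stats

from methclock.io import PatternSet, ReadPattern
from methclock.wsh import (
    CpGBlock,
    compute_score_matrix,
    epipolymorphism,
    fdrp,
    methylation_entropy,
    mhl,
    pdr,
    qfdrp,
    region_blocks,
)

from conftest import make_patternset, make_region, random_instance
from oracles import (
    oracle_fdrp,
    oracle_me,
    oracle_mhl,
    oracle_pdr,
    oracle_pm,
    oracle_qfdrp,
)


def _reads(ps, sample="S1", region="r1"):
    return ps.reads_for(sample, region)


def _block(region, start=0, stop=None):
    return CpGBlock(region.region_id, start, stop if stop is not None else region.n_cpgs)


# ---------------------------------------------------------------------------
# Hand-checked examples


def test_pdr_concordant_and_discordant_limits():
    region = make_region(4)
    ps = make_patternset([(0, "MMMM")] * 5 + [(0, "UUUU")] * 5, region=region)
    value, support = pdr(_reads(ps), _block(region), min_reads=10)
    assert value == 0.0 and support == 10
    ps = make_patternset([(0, "MUMU")] * 10, region=region)
    assert pdr(_reads(ps), _block(region), min_reads=10)[0] == 1.0


def test_pdr_short_reads_not_classified():
    region = make_region(6)
    ps = make_patternset([(0, "MU")] * 20 + [(0, "MMMM")] * 12, region=region)
    value, support = pdr(_reads(ps), _block(region), min_cpgs_per_read=4, min_reads=10)
    assert support == 12 and value == 0.0


def test_mhl_examples():
    region = make_region(3)
    assert mhl(_reads(make_patternset([(0, "MMM")], region=region)), _block(region), min_reads=1)[0] == 1.0
    # {MMM, UUU}: MH_1 = 3/6, MH_2 = 2/4, MH_3 = 1/2 -> 0.5
    ps = make_patternset([(0, "MMM"), (0, "UUU")], region=region)
    assert mhl(_reads(ps), _block(region), min_reads=1)[0] == pytest.approx(0.5)
    ps = make_patternset([(0, "UUU")] * 12, region=region)
    assert mhl(_reads(ps), _block(region), min_reads=10)[0] == 0.0


def test_pm_me_examples():
    region = make_region(4)
    allm = make_patternset([(0, "MMMM")] * 12, region=region)
    assert epipolymorphism(_reads(allm), _block(region), min_reads=10)[0] == 0.0
    assert methylation_entropy(_reads(allm), _block(region), min_reads=10)[0] == 0.0
    half = make_patternset([(0, "MMMM")] * 6 + [(0, "UUUU")] * 6, region=region)
    assert epipolymorphism(_reads(half), _block(region), min_reads=10)[0] == pytest.approx(0.5)
    assert methylation_entropy(_reads(half), _block(region), min_reads=10)[0] == pytest.approx(0.25)
    alleles = ["".join("MU"[(k >> b) & 1] for b in range(4)) for k in range(16)]
    uniform = make_patternset([(0, a) for a in alleles], region=region)
    assert methylation_entropy(_reads(uniform), _block(region), min_reads=10)[0] == pytest.approx(1.0)
    assert epipolymorphism(_reads(uniform), _block(region), min_reads=10)[0] == pytest.approx(15 / 16)


def test_fdrp_qfdrp_pair_examples():
    region = make_region(2)
    mm_uu = make_patternset([(0, "MM"), (0, "UU")], region=region)
    assert fdrp(_reads(mm_uu), region, 0, min_reads=2)[0] == 1.0
    assert qfdrp(_reads(mm_uu), region, 0, min_reads=2)[0] == 1.0
    same = make_patternset([(0, "MU"), (0, "MU")], region=region)
    assert fdrp(_reads(same), region, 0, min_reads=2)[0] == 0.0
    mm_mu = make_patternset([(0, "MM"), (0, "MU")], region=region)
    assert qfdrp(_reads(mm_mu), region, 1, min_reads=2)[0] == pytest.approx(0.5)


def test_fdrp_window_restricts_comparison():
    # CpGs 100 and 160: at window=50 only the focal CpG is shared
    region = make_region(2, spacing=60)
    ps = make_patternset([(0, "MM"), (0, "MU")], region=region)
    assert fdrp(_reads(ps), region, 0, window=50, min_reads=2)[0] == 0.0
    assert fdrp(_reads(ps), region, 0, window=100, min_reads=2)[0] == 1.0


# ---------------------------------------------------------------------------
# Oracle equivalence on random instances


def _segments(ps):
    return [(rp.first_cpg_index, rp.states) for rp in ps]


@pytest.mark.parametrize("seed", range(4))
def test_all_metrics_match_oracles_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    for _ in range(50):
        region, segs = random_instance(rng)
        ps = make_patternset(segs, region=region)
        reads = _reads(ps)
        segs = _segments(ps)
        n = region.n_cpgs
        block = _block(region)
        assert _close(mhl(reads, block, min_reads=1)[0], oracle_mhl(segs, n))
        assert _close(
            pdr(reads, block, min_cpgs_per_read=2, min_reads=1)[0],
            oracle_pdr(segs, min_cpgs_per_read=2),
        )
        if n >= 4:
            b4 = _block(region, 0, 4)
            segs4 = [(o, s[: 4 - o]) for o, s in segs if o < 4]
            assert _close(epipolymorphism(reads, b4, min_reads=1)[0], oracle_pm(segs4))
            assert _close(methylation_entropy(reads, b4, min_reads=1)[0], oracle_me(segs4))
        focal = int(rng.integers(0, n))
        pos = region.cpg_positions
        assert _close(
            fdrp(reads, region, focal, max_pairs=10_000, min_reads=1)[0],
            oracle_fdrp(segs, pos, focal),
        )
        assert _close(
            qfdrp(reads, region, focal, max_pairs=10_000, min_reads=1)[0],
            oracle_qfdrp(segs, pos, focal),
        )


def _close(a, b, tol=1e-12):
    if math.isnan(a) or math.isnan(b):
        return math.isnan(a) and math.isnan(b)
    return abs(a - b) <= tol


def test_fdrp_pair_sampling_within_binomial_ci():
    """With 12 reads (66 pairs > 40), the sampled FDRP sits inside a 99.9% CI
    of the exhaustive all-pairs value."""
    rng = np.random.default_rng(11)
    region = make_region(6)
    segs = []
    for _ in range(12):
        length = int(rng.integers(2, 7))
        first = int(rng.integers(0, 7 - length))
        segs.append((first, "".join(rng.choice(["M", "U"], size=length))))
    ps = make_patternset(segs, region=region)
    exact = oracle_fdrp(_segments(ps), region.cpg_positions, 2)
    est = fdrp(_reads(ps), region, 2, max_pairs=40, min_reads=1, rng=np.random.default_rng(5))[0]
    lo, hi = stats.binom.interval(0.999, 40, exact)
    assert lo / 40 <= est <= hi / 40


# ---------------------------------------------------------------------------
# Properties


def test_range_invariants_on_random_inputs():
    rng = np.random.default_rng(42)
    for _ in range(40):
        region, segs = random_instance(rng)
        ps = make_patternset(segs, region=region)
        reads = _reads(ps)
        block = _block(region)
        for value in (
            mhl(reads, block, min_reads=1)[0],
            pdr(reads, block, min_cpgs_per_read=1, min_reads=1)[0],
            fdrp(reads, region, 0, min_reads=1)[0],
            qfdrp(reads, region, 0, min_reads=1)[0],
        ):
            assert math.isnan(value) or 0.0 <= value <= 1.0
        if region.n_cpgs >= 4:
            b4 = _block(region, 0, 4)
            pm_v = epipolymorphism(reads, b4, min_reads=1)[0]
            me_v = methylation_entropy(reads, b4, min_reads=1)[0]
            assert math.isnan(pm_v) or 0.0 <= pm_v <= 15 / 16
            assert math.isnan(me_v) or 0.0 <= me_v <= 1.0


def test_homogeneous_read_sets_score_zero_or_extreme():
    region = make_region(4)
    for pattern, mhl_expected in (("MMMM", 1.0), ("UUUU", 0.0)):
        ps = make_patternset([(0, pattern)] * 12, region=region)
        reads = _reads(ps)
        block = _block(region)
        assert pdr(reads, block)[0] == 0.0
        assert epipolymorphism(reads, block)[0] == 0.0
        assert methylation_entropy(reads, block)[0] == 0.0
        assert fdrp(reads, region, 1)[0] == 0.0
        assert qfdrp(reads, region, 1)[0] == 0.0
        assert mhl(reads, block)[0] == mhl_expected


def test_read_order_permutation_invariance():
    rng = np.random.default_rng(3)
    region, segs = random_instance(rng, max_reads=12, max_cpgs=6)
    for metric in ("MHL", "PDR", "PM", "ME", "FDRP", "qFDRP"):
        a = compute_score_matrix(make_patternset(segs, region=region), metric, seed=9, min_reads=1)
        b = compute_score_matrix(make_patternset(segs[::-1], region=region), metric, seed=9, min_reads=1)
        assert a.values.equals(b.values)


def test_duplication_invariance_of_frequency_metrics():
    """PDR/PM/ME are epiallele-frequency statistics: duplicating every read
    must leave them unchanged."""
    rng = np.random.default_rng(8)
    region, segs = random_instance(rng, max_reads=10, max_cpgs=6)
    ps1 = make_patternset(segs, region=region)
    ps2 = make_patternset(segs + segs, region=region)
    block = _block(region)
    for fn, kwargs in (
        (pdr, {"min_cpgs_per_read": 1, "min_reads": 1}),
        (mhl, {"min_reads": 1}),
    ):
        assert _close(fn(_reads(ps1), block, **kwargs)[0], fn(_reads(ps2), block, **kwargs)[0])
    if region.n_cpgs >= 4:
        b4 = _block(region, 0, 4)
        for fn in (epipolymorphism, methylation_entropy):
            assert _close(fn(_reads(ps1), b4, min_reads=1)[0], fn(_reads(ps2), b4, min_reads=1)[0])


def test_insufficient_support_is_missing_not_zero():
    region = make_region(4)
    ps = make_patternset([(0, "MMMM")] * 5, region=region)
    value, support = pdr(_reads(ps), _block(region), min_reads=10)
    assert math.isnan(value) and support == 5
    assert math.isnan(fdrp(_reads(ps), region, 0, min_reads=10)[0])


# ---------------------------------------------------------------------------
# Score matrices


def test_score_matrix_shapes_and_units(benchmark_cohort):
    ps, _, _ = benchmark_cohort
    sm = compute_score_matrix(ps, "MHL", seed=0)
    assert list(sm.values.columns) == [r.region_id for r in ps.regions]
    sm_cpg = compute_score_matrix(ps, "MHL", seed=0, unit="cpg")
    assert sm_cpg.values.shape[1] == sum(r.n_cpgs for r in ps.regions)
    pm = compute_score_matrix(ps, "PM", seed=0)
    assert pm.values.shape[1] == sum(r.n_cpgs - 3 for r in ps.regions)
    fd = compute_score_matrix(ps, "FDRP", seed=0)
    assert fd.values.shape[1] == sum(r.n_cpgs for r in ps.regions)


def test_unknown_metric_rejected(region6):
    ps = make_patternset([(0, "MMMM")], region=region6)
    with pytest.raises(ValueError, match="MHL"):
        compute_score_matrix(ps, "pdq")


def test_score_matrix_tsv_round_trip(tmp_path, region6):
    ps = make_patternset([(0, "MMMMMM"), (0, "MUMUMU")] * 6, region=region6)
    sm = compute_score_matrix(ps, "PM", seed=4, min_reads=2)
    path = tmp_path / "pm.tsv"
    sm.to_tsv(path)
    loaded = type(sm).from_tsv(path)
    assert loaded.metric == "PM"
    assert np.allclose(loaded.values.to_numpy(), sm.values.to_numpy(), equal_nan=True)


def test_region_blocks_pm_requires_width_4(region6):
    blocks = region_blocks(region6, "PM")
    assert all(b.width == 4 for b in blocks) and len(blocks) == 3
    with pytest.raises(ValueError):
        epipolymorphism([], CpGBlock("r1", 0, 3))


def test_disorder_gradient_raises_block_metrics(benchmark_cohort):
    """PM/ME/PDR on disorder blocks increase with passage (rank corr > 0)."""
    ps, samples, truth = benchmark_cohort
    passages = {s.sample_id: s.passage for s in samples}
    disorder_regions = sorted(set(truth.loc[truth["class"] == "disorder", "region_id"]))
    assert disorder_regions == ["R3", "R4"]
    # 4-CpG windows fully inside R4's disorder block (CpG indices 0..4)
    block_windows = {"R4:13000-13030", "R4:13010-13040"}
    for metric, cols in (
        ("PDR", ["R4"]),
        ("PM", sorted(block_windows)),
        ("ME", sorted(block_windows)),
    ):
        sm = compute_score_matrix(ps, metric, seed=0)
        col = sm.values[cols].mean(axis=1)
        rho = stats.spearmanr(col, [passages[s] for s in col.index]).statistic
        assert rho > 0.3, (metric, rho)
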