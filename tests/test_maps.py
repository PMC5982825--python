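import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xomap import maps
from xomap.io import ChromosomeMeta
from conftest import make_co_table


def test_map_length_definition():
    assert maps.map_length_cM(302, 30) == pytest.approx(1006.6667, abs=1e-3)
    assert maps.map_length_cM(0, 30) == 0.0
    with pytest.raises(ValueError):
        maps.map_length_cM(10, 0)


def test_counts_invert_lengths():
    lengths = [112.5, 83.3, 13.3]
    assert maps.counts_from_lengths(lengths, 24).tolist() == [27, 20, 3]
    assert maps.counts_from_lengths(lengths, 30).tolist() == [34, 25, 4]


def test_map_table_totals_are_column_sums():
    counts = pd.DataFrame({"chromosome": ["c1", "c2"],
                           "female": [10, 14], "male": [8, 7]})
    table = maps.map_table(counts, {"female": 24, "male": 30})
    total = table[table.chromosome == "Total"].iloc[0]
    body = table[table.chromosome != "Total"]
    assert total.female_cM == pytest.approx(body.female_cM.sum())
    assert total.male_cM == pytest.approx(body.male_cM.sum())
    assert total.ratio == pytest.approx(total.female_cM / total.male_cM)


def test_map_table_zero_male_count_gives_undefined_ratio():
    counts = pd.DataFrame({"chromosome": ["c1"], "female": [5], "male": [0]})
    table = maps.map_table(counts, {"female": 24, "male": 30})
    assert np.isnan(table.iloc[0].ratio)


def test_equal_counts_give_unit_ratios_and_unit_correlation():
    co = pd.concat([
        make_co_table(["c1"] * 3 + ["c2"] * 5, [1e6] * 8, sexes=["male"] * 8),
        make_co_table(["c1"] * 3 + ["c2"] * 5, [1e6] * 8, sexes=["female"] * 8),
    ], ignore_index=True)
    table, summary = maps.per_chromosome_table(
        co, {"male": 10, "female": 10}, ["c1", "c2"])
    body = table[table.chromosome != "Total"]
    assert np.allclose(body.ratio, 1.0)
    # identical columns correlate perfectly (r = 1 by definition)
    assert summary["pearson_r_lengths"] == pytest.approx(1.0)


def test_obligate_co_probability_edge_cases():
    assert maps.obligate_co_probability(30, 30) == 1.0
    assert maps.obligate_co_probability(0, 1) == 0.5
    with pytest.raises(ValueError):
        maps.obligate_co_probability(31, 30)


def test_cv_of_identical_counts_is_zero():
    cv_f, cv_m, p = maps.cv_equality_test([7, 7, 7], [5, 5, 5, 5])
    assert cv_f == 0.0 and cv_m == 0.0 and p == 1.0


def test_cv_closed_form():
    cv_f, _, _ = maps.cv_equality_test([10, 10, 12, 12], [1, 1, 1])
    assert cv_f == pytest.approx(np.sqrt(4 / 3) / 11, abs=1e-12)


def test_cv_test_rejects_errors():
    with pytest.raises(ValueError):
        maps.cv_equality_test([1], [2, 3])
    with pytest.raises(ValueError):
        maps.cv_equality_test([0, 0], [1, 2])


def test_cv_test_calibrated_under_null():
    """Same-distribution samples reject at roughly the nominal 5% level."""
    rng = np.random.default_rng(12)
    n_rep, alpha = 1000, 0.05
    rej = 0
    for _ in range(n_rep):
        x = rng.normal(20, 3, size=24)
        y = rng.normal(20, 3, size=30)
        _, _, p = maps.cv_equality_test(x, y)
        rej += p < alpha
    rate = rej / n_rep
    sigma = np.sqrt(alpha * (1 - alpha) / n_rep)
    assert abs(rate - alpha) <= 3 * sigma


def test_folded_coordinate_examples():
    assert maps.folded_coordinate(18e6, 20e6) == pytest.approx(0.2)
    assert maps.folded_coordinate(2e6, 20e6) == pytest.approx(0.2)
    assert maps.folded_coordinate(10e6, 20e6) == pytest.approx(1.0)


def test_fold_and_bin_center_goes_to_last_segment():
    meta = {"c1": ChromosomeMeta("c1", 20_000_000)}
    co = make_co_table(["c1"], [10_000_000])
    segs = maps.fold_and_bin(co, meta, 4)["male"]
    assert segs[segs.segment == 3]["count"].iloc[0] == 1


def test_fold_and_bin_relative_lengths_sum_to_one():
    rng = np.random.default_rng(13)
    meta = {"c1": ChromosomeMeta("c1", 20_000_000),
            "c2": ChromosomeMeta("c2", 15_000_000)}
    chroms = rng.choice(["c1", "c2"], size=200)
    mids = rng.uniform(1e6, 14e6, size=200)
    co = make_co_table(chroms, mids,
                       sexes=rng.choice(["male", "female"], 200).tolist())
    for n in (2, 7, 20):
        segs = maps.fold_and_bin(co, meta, n)
        for sex in ("male", "female"):
            sums = segs[sex].groupby("chrom").rel_length.sum()
            assert np.allclose(sums, 1.0)


def test_fold_and_bin_uniform_crossovers_fill_segments_evenly():
    rng = np.random.default_rng(14)
    L, n_co, n_seg = 20_000_000, 4000, 5
    meta = {"c1": ChromosomeMeta("c1", L)}
    co = make_co_table(["c1"] * n_co, rng.uniform(0, L, n_co))
    segs = maps.fold_and_bin(co, meta, n_seg)["male"]
    p = 1 / n_seg
    band = 3 * np.sqrt(p * (1 - p) / n_co)
    assert np.all(np.abs(segs.rel_length - p) <= band)


def test_fold_and_bin_rejects_bad_scale():
    with pytest.raises(ValueError):
        maps.fold_and_bin(make_co_table(["c1"], [1e6]),
                          {"c1": ChromosomeMeta("c1", 2_000_000)}, 1)


def test_sex_segment_correlation_toy_limits():
    perfect_f = pd.DataFrame({"chrom": ["c"] * 4, "segment": range(4),
                              "rel_length": [0.4, 0.3, 0.2, 0.1]})
    perfect_m = perfect_f.copy()
    r, p = maps.sex_segment_correlation(perfect_f, perfect_m)
    assert r == pytest.approx(1.0)
    # anti-mirrored: one sex distal, the other central
    f2 = pd.DataFrame({"chrom": ["c1", "c1", "c2", "c2"],
                       "segment": [0, 1, 0, 1],
                       "rel_length": [1.0, 0.0, 0.9, 0.1]})
    m2 = f2.copy()
    m2["rel_length"] = 1 - m2.rel_length
    r, _ = maps.sex_segment_correlation(f2, m2)
    assert r == pytest.approx(-1.0)


def test_sex_segment_correlation_zero_variance_undefined():
    flat = pd.DataFrame({"chrom": ["c"] * 4, "segment": range(4),
                         "rel_length": [0.25] * 4})
    r, p = maps.sex_segment_correlation(flat, flat)
    assert np.isnan(r) and np.isnan(p)


def test_shared_telomere_effect_detected_across_scales():
    """When both sexes concentrate crossovers distally, folded segment maps
    correlate positively at the coarsest scale in near-all replicates."""
    rng = np.random.default_rng(15)
    meta = {f"c{i}": ChromosomeMeta(f"c{i}", 20_000_000) for i in range(8)}
    wins = 0
    for rep in range(20):
        rows = []
        for sex in ("male", "female"):
            for c in meta:
                # distal-biased positions: fold ~ Beta(1, 3)
                folded = rng.beta(1, 3, size=30)
                side = rng.random(30) < 0.5
                mids = np.where(side, folded * 1e7, 2e7 - folded * 1e7)
                rows.append(make_co_table([c] * 30, mids, sexes=[sex] * 30))
        co = pd.concat(rows, ignore_index=True)
        segs = maps.fold_and_bin(co, meta, 2)
        r, _ = maps.sex_segment_correlation(segs["female"], segs["male"])
        wins += r > 0
    assert wins >= 19


ARM_META = {"c1": ChromosomeMeta("c1", 20_000_000, 5_000_000)}


def test_arm_rates_proportional_counts_give_zero_chisq():
    # 5 short-arm and 15 long-arm COs on 5 Mb / 15 Mb arms
    mids = np.concatenate([np.linspace(1e6, 4e6, 5),
                           np.linspace(6e6, 19e6, 15)])
    co = make_co_table(["c1"] * 20, mids)
    arms, tests = maps.arm_rates(co, ARM_META)
    row = arms[arms.parent_sex == "male"].iloc[0]
    assert row.n_short == 5 and row.n_long == 15
    assert row.rate_short_per_mb == pytest.approx(1.0)
    assert row.rate_long_per_mb == pytest.approx(1.0)
    assert tests["male"]["chi2"] == pytest.approx(0.0, abs=1e-12)


def test_arm_rates_all_long_closed_form():
    # expected 25% short arm; all n COs on the long arm gives chi2 = n/3
    n = 24
    co = make_co_table(["c1"] * n, np.linspace(6e6, 19e6, n))
    _, tests = maps.arm_rates(co, ARM_META)
    assert tests["male"]["chi2"] == pytest.approx(n / 3)
    assert tests["male"]["p"] == pytest.approx(stats.chi2.sf(n / 3, 1))


def test_arm_rates_skip_sexless_cases():
    co = make_co_table(["c1"], [1e6], sexes=["male"])
    _, tests = maps.arm_rates(co, ARM_META)
    assert tests["female"] is None  # no female crossovers -> test skipped


def test_arm_rates_exclude_no_centromere_and_sex_chromosomes():
    meta = {"c1": ChromosomeMeta("c1", 20_000_000, 5_000_000),
            "c2": ChromosomeMeta("c2", 20_000_000, None),
            "c9": ChromosomeMeta("c9", 20_000_000, 5_000_000, True)}
    co = make_co_table(["c1", "c2", "c9"], [6e6, 6e6, 6e6])
    arms, tests = maps.arm_rates(co, meta)
    assert set(arms.chrom) == {"c1", "c9"}  # c2 has no centromere
    # sex chromosome contributes a rate row but not the pooled deficit test
    assert tests["male"]["observed_short"] == 0


def test_reference_map_lengths_table_loads():
    ref = maps.load_reference_map_lengths()
    assert len(ref) == 21
    assert ref.female_cM.sum() == pytest.approx(1650.0, abs=0.3)
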