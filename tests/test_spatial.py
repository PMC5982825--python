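import numpy as np
import pandas as pd
import pytest

from xomap import spatial
from xomap.io import ChromosomeMeta
from conftest import make_co_table


def _meta(**kw):
    base = {"c1": ChromosomeMeta("c1", 20_000_000, 5_000_000),
            "c2": ChromosomeMeta("c2", 30_000_000, 15_000_000)}
    base.update(kw)
    return base


def test_covariate_arithmetic():
    cov = spatial.build_covariates(_meta(), n_segments=10)
    seg0 = cov[(cov.chrom == "c1") & (cov.segment == 0)].iloc[0]
    assert seg0.center == pytest.approx(1_000_000)
    assert seg0.d_telo == pytest.approx(0.1)
    assert seg0.d_centro_mb == pytest.approx(4.0)
    # scaled by the max arm length over included chromosomes (15 Mb here)
    assert seg0.d_centro == pytest.approx(4.0 / 15.0)
    assert seg0.d_center == pytest.approx(0.9)


def test_metacentric_centromere_and_center_distances_rank_identical():
    meta = {"c": ChromosomeMeta("c", 20_000_000, 10_000_000),
            "d": ChromosomeMeta("d", 18_000_000, 9_000_000)}
    cov = spatial.build_covariates(meta)
    sub = cov[cov.chrom == "c"]
    assert (sub.d_centro.rank() == sub.d_center.rank()).all()


def test_covariates_exclude_sexchrom_and_missing_centromere():
    meta = _meta(c3=ChromosomeMeta("c3", 20_000_000, None),
                 c9=ChromosomeMeta("c9", 20_000_000, 5_000_000, True))
    cov = spatial.build_covariates(meta)
    assert set(cov.chrom) == {"c1", "c2"}


def test_covariates_invariant_to_chromosome_order():
    meta = _meta()
    cov_a = spatial.build_covariates(meta)
    cov_b = spatial.build_covariates(dict(reversed(list(meta.items()))))
    pd.testing.assert_frame_equal(cov_a, cov_b)


def test_long_arm_scope_spans_centromere_to_far_telomere():
    cov = spatial.build_covariates(_meta(), n_segments=5, scope="long_arm")
    c1 = cov[cov.chrom == "c1"]
    assert c1.start.min() == pytest.approx(5_000_000)
    assert c1.end.max() == pytest.approx(20_000_000)
    # acrocentric with long arm on the left
    meta = {"c": ChromosomeMeta("c", 20_000_000, 16_000_000),
            "d": ChromosomeMeta("d", 18_000_000, 9_000_000)}
    cov = spatial.build_covariates(meta, n_segments=5, scope="long_arm")
    c = cov[cov.chrom == "c"]
    assert c.start.min() == pytest.approx(0.0)
    assert c.end.max() == pytest.approx(16_000_000)


def test_count_cos_in_segments():
    cov = spatial.build_covariates(_meta(), n_segments=10)
    co = make_co_table(["c1", "c1", "c2"], [1.5e6, 1.6e6, 29e6])
    out = spatial.count_cos_in_segments(co, cov, sex="male")
    assert out[(out.chrom == "c1") & (out.segment == 0)].n_co.iloc[0] == 2
    assert out[(out.chrom == "c2") & (out.segment == 9)].n_co.iloc[0] == 1
    assert out.n_co.sum() == 3


def _sim_counts(meta, rng, b_telo=0.0, b_centro=0.0, noise=0.7):
    cov = spatial.build_covariates(meta)
    chrom_eff = {c: rng.normal(0, 0.5) for c in cov.chrom.unique()}
    y = (6.0 - b_telo * cov.d_telo - b_centro * (1 - cov.d_centro)
         + cov.chrom.map(chrom_eff) + rng.normal(0, noise, len(cov)))
    return cov.assign(n_co=y)


def test_ledger_aic_identity_and_monotone_loglik():
    rng = np.random.default_rng(21)
    meta = {f"c{i}": ChromosomeMeta(f"c{i}", int(L), int(L * 0.25))
            for i, L in enumerate(np.linspace(30e6, 15e6, 8))}
    df = _sim_counts(meta, rng, b_telo=3.0)
    ledger = spatial.fit_model_ledger(df, "n_co").set_index("model")
    # AIC = 2k - 2 lnL exactly
    for _, row in ledger.iterrows():
        assert row.aic == pytest.approx(2 * row.k - 2 * row.loglik)
    # adding a fixed effect never decreases the maximized likelihood
    assert ledger.loc["both", "loglik"] >= ledger.loc["telomere", "loglik"] - 1e-6
    assert ledger.loc["both", "loglik"] >= ledger.loc["centromere", "loglik"] - 1e-6
    assert ledger.loc["telomere", "loglik"] >= ledger.loc["null", "loglik"] - 1e-6
    assert ledger.delta_aic.min() == pytest.approx(0.0)


def test_ledger_recovers_exact_linear_response():
    """Zero noise: the telomere model reproduces the generating coefficient."""
    import statsmodels.api as sm
    meta = {f"c{i}": ChromosomeMeta(f"c{i}", int(L), int(L * 0.25))
            for i, L in enumerate(np.linspace(30e6, 20e6, 4))}
    cov = spatial.build_covariates(meta)
    df = cov.assign(n_co=10.0 - 4.0 * cov.d_telo)
    exog = sm.add_constant(df[["d_telo"]])
    res = sm.MixedLM(df.n_co, exog, groups=df.chrom).fit(reml=False)
    assert res.params["d_telo"] == pytest.approx(-4.0, abs=1e-4)
    assert res.params["const"] == pytest.approx(10.0, abs=1e-4)


def test_ledger_needs_multiple_groups():
    meta = {"c1": ChromosomeMeta("c1", 20_000_000, 5_000_000)}
    cov = spatial.build_covariates(meta).assign(n_co=1.0)
    with pytest.raises(ValueError):
        spatial.fit_model_ledger(cov, "n_co")


def test_absolute_distance_model_beats_relative_when_mechanism_absolute():
    """Counts suppressed by absolute centromere distance favour the
    max-arm-scaled covariate over the per-chromosome-scaled one."""
    rng = np.random.default_rng(22)
    meta = {f"c{i}": ChromosomeMeta(f"c{i}", int(L), int(L * 0.2))
            for i, L in enumerate(np.linspace(32e6, 16e6, 10))}
    models = {"absolute": ["d_centro"], "relative": ["d_centro_rel"]}
    wins = 0
    for rep in range(5):
        cov = spatial.build_covariates(meta)
        chrom_eff = {c: rng.normal(0, 0.3) for c in cov.chrom.unique()}
        # recovery of crossovers with absolute distance from the centromere:
        # one shared slope per Mb across chromosomes of different lengths
        y = (0.3 * cov.d_centro_mb
             + cov.chrom.map(chrom_eff) + rng.normal(0, 0.4, len(cov)))
        ledger = spatial.fit_model_ledger(cov.assign(n_co=y), "n_co",
                                          models=models)
        wins += spatial.best_model(ledger) == "absolute"
    assert wins >= 4


def test_fst_star_scaling_examples():
    df = pd.DataFrame({"chrom": ["c1"] * 3, "start": [0, 1, 2],
                       "end": [1, 2, 3], "fst": [0.1, 0.2, 0.3]})
    out = spatial.fst_star(df)
    assert np.allclose(out.fst_star, [0.5, 1.0, 1.5])
    flat = df.assign(fst=0.2)
    assert np.allclose(spatial.fst_star(flat).fst_star, 1.0)


def test_fst_star_mean_is_one_per_chromosome():
    rng = np.random.default_rng(23)
    df = pd.DataFrame({
        "chrom": np.repeat([f"c{i}" for i in range(6)], 40),
        "start": np.tile(np.arange(40) * 100_000, 6),
        "end": np.tile((np.arange(40) + 1) * 100_000, 6),
        "fst": rng.uniform(0.01, 0.8, 240)})
    out = spatial.fst_star(df)
    for _, grp in out.groupby("chrom"):
        assert abs(grp.fst_star.mean() - 1.0) <= 1e-9


def test_fst_star_excludes_nonpositive_mean_chromosome():
    df = pd.DataFrame({"chrom": ["bad"] * 2 + ["ok"] * 2,
                       "start": [0, 1, 0, 1], "end": [1, 2, 1, 2],
                       "fst": [-0.1, 0.1, 0.2, 0.4]})
    out = spatial.fst_star(df)
    assert set(out.chrom) == {"ok"}


def test_recomb_differentiation_correlation_limits():
    seg = pd.DataFrame({"segment": range(10),
                        "rel_length": np.linspace(0.2, 0.02, 10)})
    fst = pd.DataFrame({"segment": range(10),
                        "fst_star": 2.0 - 3.0 * seg.rel_length})
    r, p = spatial.recomb_differentiation_correlation(seg, fst)
    assert r == pytest.approx(-1.0)
    flat = fst.assign(fst_star=1.0)
    r, p = spatial.recomb_differentiation_correlation(seg, flat)
    assert np.isnan(r)


def test_recomb_differentiation_correlation_under_linked_selection_toy():
    rng = np.random.default_rng(24)
    neg = 0
    for rep in range(20):
        rate = np.abs(rng.normal(0.1, 0.05, 10))
        seg = pd.DataFrame({"segment": range(10), "rel_length": rate})
        fst = pd.DataFrame({"segment": range(10),
                            "fst_star": 1.5 - 4.0 * rate
                            + rng.normal(0, 0.05, 10)})
        r, _ = spatial.recomb_differentiation_correlation(seg, fst)
        neg += r < 0
    assert neg >= 19


def test_independent_tracks_correlate_near_zero_on_average():
    rng = np.random.default_rng(25)
    rs = []
    for rep in range(300):
        seg = pd.DataFrame({"segment": range(10),
                            "rel_length": rng.random(10)})
        fst = pd.DataFrame({"segment": range(10),
                            "fst_star": rng.random(10)})
        r, _ = spatial.recomb_differentiation_correlation(seg, fst)
        rs.append(r)
    assert abs(np.mean(rs)) <= 3 * np.std(rs) / np.sqrt(len(rs))


def test_fst_star_by_folded_segment_maps_window_centers():
    meta = {"c1": ChromosomeMeta("c1", 2_000_000)}
    fst = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 900_000],
                        "end": [100_000, 1_100_000],
                        "fst_star": [0.5, 1.5]})
    seg = spatial.fst_star_by_folded_segment(fst, meta, n_segments=2)
    # window centers at 50 kb (folded 0.05 -> segment 0) and 1 Mb (center ->
    # folded 1.0 -> last segment)
    assert seg[seg.segment == 0].fst_star.iloc[0] == pytest.approx(0.5)
    assert seg[seg.segment == 1].fst_star.iloc[0] == pytest.approx(1.5)
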