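"""Differential expression: moderated t, DPC likelihood-ratio test, BH, metrics."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit, log_expit

from protdpc import (
    DifferentialExpression,
    IntensityMatrix,
    SimConfig,
    benjamini_hochberg,
    dpc_lrt,
    evaluate_de,
    missing_loglik,
    moderated_t_test,
    simulate_dataset,
)


# ---------- Benjamini-Hochberg ------------------------------------------------

def bh_bruteforce(p):
    """Textbook step-up rule, quadratic-time."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def test_bh_hand_examples():
    assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
    np.testing.assert_allclose(
        benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_bruteforce(rng):
    for _ in range(300):
        p = rng.random(rng.integers(1, 60))
        np.testing.assert_allclose(benjamini_hochberg(p), bh_bruteforce(p),
                                   atol=1e-12)


def test_bh_propagates_nans():
    out = benjamini_hochberg([0.01, np.nan, 0.5])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], bh_bruteforce([0.01, 0.5]))


# ---------- missing-value likelihood -----------------------------------------

def test_missing_loglik_flat_dpc():
    v = missing_loglik(8.0, 0.09, beta0=-1.0, beta1=0.0)
    assert v == pytest.approx(float(log_expit(1.0)), abs=1e-12)


def test_missing_loglik_degenerate_variance():
    v = missing_loglik(8.0, 0.0, beta0=-6.0, beta1=0.8)
    assert v == pytest.approx(float(log_expit(-(-6.0 + 0.8 * 8.0))), abs=1e-12)


def test_quadrature_matches_dense_integration():
    # 100-point parameter grid; the quadrature must track adaptive dense
    # integration to 1e-8 absolute in the log
    worst = 0.0
    for mu in np.linspace(5, 12, 5):
        for s2 in (0.04, 0.09, 0.25, 0.5, 1.0):
            for b1 in (0.2, 0.8, 1.2, 1.5):
                b0 = -b1 * 8.5
                sd = np.sqrt(s2)
                val, _ = integrate.quad(
                    lambda y: np.exp(-((y - mu) ** 2) / (2 * s2))
                    / np.sqrt(2 * np.pi * s2) * expit(-(b0 + b1 * y)),
                    mu - 12 * sd, mu + 12 * sd, epsabs=1e-14, limit=200)
                worst = max(worst, abs(missing_loglik(mu, s2, b0, b1)
                                       - np.log(val)))
    assert worst < 1e-8


# ---------- moderated t -------------------------------------------------------

def test_extreme_effect_is_significant(rng):
    m, k = 100, 6
    y = rng.normal(8.0, 0.3, (m, 2 * k))
    y[0, k:] += 3.0  # a 10-sigma separation
    mat = IntensityMatrix(y, np.ones_like(y))
    res = moderated_t_test(mat, np.repeat([1, 2], k))
    assert res.table["p_value"][0] < 1e-10


def test_moderated_t_matches_limma(tmp_path):
    """Independent oracle: Bioconductor limma on the same matrix with NAs."""
    ds = simulate_dataset(SimConfig(n_features=250, n_samples_per_group=4,
                                    n_de=25, seed=42))
    mat = ds.observed
    frame = pd.DataFrame(np.where(mat.mask == 1, mat.values, np.nan),
                         index=mat.feature_ids, columns=mat.sample_ids)
    frame.to_csv(tmp_path / "mat.tsv", sep="\t")
    np.savetxt(tmp_path / "groups.txt", ds.group_labels, fmt="%d")
    rscript = textwrap.dedent("""
        suppressMessages(library(limma))
        y <- as.matrix(read.delim("mat.tsv", row.names=1))
        g <- factor(scan("groups.txt", quiet=TRUE))
        fit <- eBayes(lmFit(y, model.matrix(~g)))
        out <- data.frame(feature_id=rownames(y), t=fit$t[,2], p=fit$p.value[,2])
        write.table(out, "r_res.tsv", sep="\t", row.names=FALSE, quote=FALSE)
    """)
    (tmp_path / "cmp.R").write_text(rscript)
    proc = subprocess.run(["Rscript", "cmp.R"], cwd=tmp_path,
                          capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    r = pd.read_csv(tmp_path / "r_res.tsv", sep="\t")
    res = moderated_t_test(mat, ds.group_labels)
    merged = res.table.merge(r, on="feature_id")
    ok = np.isfinite(merged["stat"]) & np.isfinite(merged["t"])
    assert ok.sum() > 150
    np.testing.assert_allclose(merged.loc[ok, "stat"], merged.loc[ok, "t"],
                               rtol=1e-5, atol=1e-6)
    np.testing.assert_allclose(merged.loc[ok, "p_value"], merged.loc[ok, "p"],
                               atol=1e-6)


def test_moderated_t_null_calibration():
    ds = simulate_dataset(SimConfig(n_features=4000, n_de=0, seed=21))
    res = moderated_t_test(ds.complete, ds.group_labels)
    p = res.p_values
    rate = np.mean(p < 0.05)
    se = np.sqrt(0.05 * 0.95 / len(p))
    assert abs(rate - 0.05) < 4 * se


def test_min_data_rules_give_na():
    nan = np.nan
    y = np.array([[8, 9, nan, nan],   # one group empty
                  [8, nan, 9, nan],   # 1+1: under 3 total
                  [8, 9, 9.5, nan],   # testable
                  [8, 9, 9.5, 10]])
    mat = IntensityMatrix(y, np.isfinite(y))
    res = moderated_t_test(mat, [1, 1, 2, 2])
    assert np.isnan(res.p_values[:2]).all()
    assert np.isfinite(res.p_values[2:]).all()


# ---------- DPC likelihood-ratio test ----------------------------------------

def test_lrt_equals_known_variance_lrt_when_fully_observed(small_sim):
    res = dpc_lrt(small_sim.observed, small_sim.group_labels, (-6.0, 0.8))
    de = DifferentialExpression(small_sim.observed, small_sim.group_labels)
    full = (de.n1 + de.n2) == small_sim.observed.n_samples
    # no missing terms: LR reduces to the classic normal LRT with plug-in
    # variance, n1*n2/n * (mean difference)^2 / sigma2
    with np.errstate(invalid="ignore"):
        expect = (de.n1 * de.n2 / (de.n1 + de.n2)
                  * (de.mean2 - de.mean1) ** 2 / de.s2_mod)
    got = res.table["stat"].to_numpy()
    np.testing.assert_allclose(got[full], expect[full], atol=1e-7)


def test_lrt_null_calibration_permuted_labels():
    ds = simulate_dataset(SimConfig(n_features=4000, n_de=0, seed=22))
    from protdpc import fit_dpc

    fit = fit_dpc(ds.observed)
    rng = np.random.default_rng(1)
    groups = rng.permutation(ds.group_labels)
    res = dpc_lrt(ds.observed, groups, fit.beta)
    p = res.p_values
    p = p[np.isfinite(p)]
    rate = np.mean(p < 0.05)
    se = np.sqrt(0.05 * 0.95 / len(p))
    # small-sample features make the chi-square reference slightly liberal;
    # allow a one-sided excess of a few MC standard errors
    assert rate < 0.05 + 6 * se
    assert rate > 0.05 - 4 * se


def test_lrt_tests_superset_of_moderated_t(small_sim):
    rt = moderated_t_test(small_sim.observed, small_sim.group_labels)
    rl = dpc_lrt(small_sim.observed, small_sim.group_labels, (-6.0, 0.8))
    rs = dpc_lrt(small_sim.observed, small_sim.group_labels, (-6.0, 0.8),
                 single_group_features=True)
    t_ok = np.isfinite(rt.p_values)
    l_ok = np.isfinite(rl.p_values)
    s_ok = np.isfinite(rs.p_values)
    # never loses a feature the NA-dropping pipeline can test
    assert np.all(l_ok[t_ok])
    # the permissive rule additionally tests one-group-only features
    de = DifferentialExpression(small_sim.observed, small_sim.group_labels)
    one_group = ((de.n1 == 0) ^ (de.n2 == 0)) & ((de.n1 + de.n2) >= 1)
    assert one_group.sum() > 0
    assert np.all(s_ok[one_group])
    assert not np.any(l_ok[one_group])


def test_lrt_statistics_nonnegative(small_sim):
    res = dpc_lrt(small_sim.observed, small_sim.group_labels, (-6.0, 0.8),
                  single_group_features=True)
    stats_ = res.table["stat"].to_numpy()
    assert np.all(stats_[np.isfinite(stats_)] >= 0)
    fdr = res.fdr
    fin = np.isfinite(fdr)
    assert np.all((fdr[fin] >= 0) & (fdr[fin] <= 1))


def test_power_ordering_across_seeds():
    """Complete-data power > DPC-LRT power > NA-dropping power, on average."""
    tpr = {"complete": [], "dpc": [], "missing": []}
    for seed in (31, 32, 33):
        ds = simulate_dataset(SimConfig(n_features=4000, n_de=400, seed=seed))
        from protdpc import fit_dpc

        fit = fit_dpc(ds.observed)
        tpr["complete"].append(
            evaluate_de(moderated_t_test(ds.complete, ds.group_labels),
                        ds.de_labels)["tpr"])
        tpr["missing"].append(
            evaluate_de(moderated_t_test(ds.observed, ds.group_labels),
                        ds.de_labels)["tpr"])
        tpr["dpc"].append(
            evaluate_de(dpc_lrt(ds.observed, ds.group_labels, fit.beta),
                        ds.de_labels)["tpr"])
    assert np.mean(tpr["complete"]) > np.mean(tpr["dpc"])
    assert np.mean(tpr["dpc"]) > np.mean(tpr["missing"])


# ---------- evaluation --------------------------------------------------------

def _fake_results(p):
    from protdpc.detest import DEResults

    p = np.asarray(p, dtype=float)
    tab = pd.DataFrame({
        "feature_id": [f"f{i}" for i in range(len(p))],
        "effect": 0.0, "stat": 0.0, "p_value": p,
        "fdr": benjamini_hochberg(p), "n_obs_g1": 3, "n_obs_g2": 3,
        "method": "fake",
    })
    return DEResults(tab, "fake")


def test_perfect_detector_metrics():
    labels = np.array([1, -1, 0, 0, 0])
    res = _fake_results([1e-9, 1e-9, 0.9, 0.8, 0.7])
    out = evaluate_de(res, labels)
    assert out["tpr"] == 1.0
    assert out["fdr"] == 0.0


def test_silent_detector_metrics():
    labels = np.array([1, -1, 0, 0])
    out = evaluate_de(_fake_results([0.9, 0.9, 0.9, 0.9]), labels)
    assert out["tpr"] == 0.0
    assert out["fdr"] == 0.0  # max(1, discoveries) convention


def test_label_misalignment_errors():
    with pytest.raises(ValueError, match="misaligned"):
        evaluate_de(_fake_results([0.5, 0.5]), np.array([1, 0, 0]))


def test_pure_null_bh_makes_few_discoveries(rng):
    p = rng.random(2000)
    out = evaluate_de(_fake_results(p), np.zeros(2000))
    assert out["n_discoveries"] <= 5
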