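"""Normalization, dispersion, both testing paths, FDR and consensus rules."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, special, stats

from aleuro.containers import CountMatrix, SimConfig
from aleuro import synthio
from aleuro.deg import (DesignSpec, NormFactors, bh_adjust,
                        call_consensus_degs, estimate_dispersion,
                        filter_expressed, moderated_t_test, nb_glm_lrt,
                        run_deg, tmm_factors, voom_transform)
from aleuro.expression import compute_tpm, summarize_expression


def _cm_from_array(arr, prefix=("AL", "ST")):
    """Paired count matrix: columns alternate AL/ST within blocks."""
    arr = np.asarray(arr)
    genes = pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene")
    nblocks = arr.shape[1] // 2
    cols, sheet = [], []
    for b in range(1, nblocks + 1):
        for t in prefix:
            sid = f"{t}_r{b}"
            cols.append(sid)
            sheet.append({"sample": sid, "tissue": t, "timepoint": 18,
                          "replicate_block": f"b{b}"})
    counts = pd.DataFrame(arr, index=genes, columns=cols)
    lengths = pd.Series(1000.0, index=genes)
    return CountMatrix(counts, lengths,
                       pd.DataFrame(sheet).set_index("sample"))


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def test_tmm_identical_columns():
    cm = _cm_from_array(np.tile([[10], [20], [30], [40]], (1, 4)))
    f = tmm_factors(cm)
    assert np.allclose(f.factors, 1.0)


def test_tmm_pure_depth_difference():
    base = np.array([[10], [25], [40], [100], [7], [300]])
    cm = _cm_from_array(np.hstack([base, 2 * base]))
    f = tmm_factors(cm)
    assert np.allclose(f.factors, 1.0, atol=1e-12)


def test_tmm_matches_direct_trimmed_mean():
    """Independent step-by-step evaluation of the trimmed weighted mean."""
    rng = np.random.default_rng(0)
    y = rng.poisson(50, size=(40, 2)).astype(float)
    y[0, 0] = 5000  # dominant gene induces composition bias
    cm = _cm_from_array(y)
    f = tmm_factors(cm).factors.to_numpy()

    lib = y.sum(axis=0)
    uq = np.array([np.quantile(c[c > 0] / n, 0.75)
                   for c, n in zip(y.T, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    i = 1 - ref
    ok = (y[:, i] > 0) & (y[:, ref] > 0)
    pi, pr = y[ok, i] / lib[i], y[ok, ref] / lib[ref]
    m, a = np.log2(pi / pr), 0.5 * np.log2(pi * pr)
    w = (lib[i] - y[ok, i]) / (lib[i] * y[ok, i]) \
        + (lib[ref] - y[ok, ref]) / (lib[ref] * y[ok, ref])
    keep = ((m >= np.quantile(m, 0.3)) & (m <= np.quantile(m, 0.7))
            & (a >= np.quantile(a, 0.05)) & (a <= np.quantile(a, 0.95)))
    raw = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    expect = np.array([1.0, 1.0])
    expect[i] = raw
    expect /= np.exp(np.mean(np.log(expect)))
    assert np.allclose(f, expect)


def test_tmm_matches_edger_cross_check(tmp_path):
    """edgeR's calcNormFactors as an independent oracle on a fixture."""
    cfg = SimConfig(seed=17, n_genes=400, timepoints=(18,),
                    n_replicates_per_tissue=3, de_fraction=0.2,
                    log2fc_effect=3.0)
    cm, _ = synthio.simulate_rnaseq_counts(cfg)
    path = tmp_path / "counts.tsv"
    cm.counts.to_csv(path, sep="\t")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- read.delim("{path}", row.names=1);'
        'f <- calcNormFactors(DGEList(counts=as.matrix(x)))'
        '$samples$norm.factors;'
        'cat(sprintf("%.8f", f), sep="\\n")')
    res = subprocess.run(["Rscript", "-e", script],
                         capture_output=True, text=True, check=True)
    edger = np.array([float(v) for v in res.stdout.split()])
    mine = tmm_factors(cm).factors.to_numpy()
    assert np.allclose(mine, edger, atol=1e-4)


def test_tmm_all_zero_sample_errors():
    arr = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="all-zero"):
        tmm_factors(_cm_from_array(arr))


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def test_common_dispersion_poisson_limit():
    cfg = SimConfig(seed=19, n_genes=2000, de_fraction=0.0,
                    nb_dispersion=0.0, timepoints=(18,),
                    n_replicates_per_tissue=4)
    cm, _ = synthio.simulate_rnaseq_counts(cfg)
    sub = filter_expressed(cm)
    design = DesignSpec.from_samples(sub.samples)
    disp = estimate_dispersion(sub, design)
    assert disp.common < 0.01


def test_constant_gene_tagwise_finite():
    arr = np.array([[50, 50, 50, 50, 50, 50],
                    [30, 60, 45, 80, 20, 55],
                    [500, 450, 520, 480, 510, 490],
                    [5, 8, 3, 9, 6, 7]])
    cm = _cm_from_array(arr)
    design = DesignSpec.from_samples(cm.samples)
    disp = estimate_dispersion(cm, design)
    assert np.isfinite(disp.tagwise).all()
    assert (disp.tagwise >= 0).all()


def test_zero_residual_df_errors():
    arr = np.array([[10, 20], [30, 40], [1, 2]])
    cm = _cm_from_array(arr)
    design = DesignSpec.from_samples(cm.samples)
    with pytest.raises(ValueError, match="residual"):
        estimate_dispersion(cm, design)


# ---------------------------------------------------------------------------
# NB GLM LRT
# ---------------------------------------------------------------------------

def test_null_gene_has_unit_pvalue():
    arr = np.array([[100, 100, 100, 100, 100, 100],
                    [40, 60, 55, 45, 50, 50],
                    [10, 300, 12, 280, 9, 310]])
    cm = _cm_from_array(arr)
    design = DesignSpec.from_samples(cm.samples)
    # equal effective library sizes so constant counts mean a true null
    factors = NormFactors(pd.Series(1.0, index=cm.sample_ids),
                          pd.Series(1e5, index=cm.sample_ids))
    res = nb_glm_lrt(cm, design, 0.1, factors)
    assert res.loc["g0", "lr_stat"] == pytest.approx(0.0, abs=1e-4)
    assert res.loc["g0", "p_nb"] == pytest.approx(1.0, abs=1e-3)
    assert res.loc["g2", "p_nb"] < 0.01


def test_two_group_log2fc_matches_group_mean_ratio():
    """Saturated two-group fit: log2fc = log2 of normalized mean ratio."""
    rng = np.random.default_rng(1)
    y = np.column_stack([rng.poisson(200, (30, 3)),
                         rng.poisson(50, (30, 3))]).astype(float)
    genes = pd.Index([f"g{i}" for i in range(30)], name="gene")
    cols = [f"AL_r{i}" for i in (1, 2, 3)] + [f"ST_r{i}" for i in (1, 2, 3)]
    sheet = pd.DataFrame({
        "tissue": ["AL"] * 3 + ["ST"] * 3, "timepoint": 18,
        "replicate_block": ["b1", "b2", "b3"] * 2}, index=cols)
    cm = CountMatrix(pd.DataFrame(y, index=genes, columns=cols),
                     pd.Series(1000.0, index=genes), sheet)
    X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0]])
    design = DesignSpec(matrix=X, reduced=X[:, :1], condition_index=1,
                        sample_ids=cm.sample_ids,
                        condition=pd.Series([1, 1, 1, 0, 0, 0], index=cols))
    lib = 100_000.0
    factors = NormFactors(factors=pd.Series(1.0, index=cols),
                          library_sizes=pd.Series(lib, index=cols))
    res = nb_glm_lrt(cm, design, 0.1, factors)
    expect = np.log2(y[:, :3].mean(axis=1) / y[:, 3:].mean(axis=1))
    assert np.allclose(res["log2fc"], expect, atol=1e-6)


def test_swapping_condition_labels_negates_log2fc():
    cfg = SimConfig(seed=23, n_genes=300, de_fraction=0.2,
                    timepoints=(18,), n_replicates_per_tissue=3)
    cm, _ = synthio.simulate_rnaseq_counts(cfg)
    sub = filter_expressed(cm)
    design = DesignSpec.from_samples(sub.samples)
    f = tmm_factors(sub)
    res = nb_glm_lrt(sub, design, 0.1, f)

    swapped = sub.samples.copy()
    swapped["tissue"] = swapped["tissue"].map({"AL": "ST", "ST": "AL"})
    cm2 = CountMatrix(sub.counts, sub.gene_lengths, swapped)
    res2 = nb_glm_lrt(cm2, DesignSpec.from_samples(swapped), 0.1, f)
    assert np.allclose(res["log2fc"], -res2["log2fc"], atol=1e-6)
    assert np.allclose(res["p_nb"], res2["p_nb"], atol=1e-8)


# ---------------------------------------------------------------------------
# voom + moderated t
# ---------------------------------------------------------------------------

def test_logcpm_zero_count_formula():
    arr = np.array([[0, 0, 0, 0, 0, 1],
                    [100, 120, 90, 110, 95, 105],
                    [50, 60, 40, 55, 45, 65]])
    cm = _cm_from_array(arr)
    design = DesignSpec.from_samples(cm.samples)
    lib = 1e6 - 1
    factors = NormFactors(
        factors=pd.Series(1.0, index=cm.sample_ids),
        library_sizes=pd.Series(lib, index=cm.sample_ids))
    logcpm, _ = voom_transform(cm, design, factors)
    assert logcpm.loc["g0"].iloc[0] == pytest.approx(np.log2(0.5))


def test_logcpm_depth_invariance():
    """Doubling counts and libsizes barely moves log-CPM.

    The pseudo-count perturbation is ~0.5/(2y ln 2) per observation, so the
    1e-3 bound holds from counts of a few hundred upward.
    """
    arr = np.array([[1000, 1500, 1200, 1300, 1400, 1100],
                    [5000, 4900, 5100, 4950, 5050, 4980]])
    cm = _cm_from_array(arr)
    cm2 = _cm_from_array(2 * arr)
    design = DesignSpec.from_samples(cm.samples)
    f1 = NormFactors(pd.Series(1.0, index=cm.sample_ids),
                     pd.Series(1e6, index=cm.sample_ids))
    f2 = NormFactors(pd.Series(1.0, index=cm.sample_ids),
                     pd.Series(2e6, index=cm.sample_ids))
    l1, _ = voom_transform(cm, design, f1)
    l2, _ = voom_transform(cm2, design, f2)
    assert np.abs(l1.to_numpy() - l2.to_numpy()).max() < 1e-3


def test_voom_weights_flat_for_homoscedastic_data():
    """High-abundance NB data is variance-flat on the log scale."""
    cfg = SimConfig(seed=29, n_genes=500, de_fraction=0.0,
                    nb_dispersion=0.1, abundance_sdlog=0.3,
                    timepoints=(18,), n_replicates_per_tissue=4)
    cm, _ = synthio.simulate_rnaseq_counts(cfg)
    sub = filter_expressed(cm, min_count=50)
    design = DesignSpec.from_samples(sub.samples)
    _, w = voom_transform(sub, design)
    cv = w.to_numpy().std() / w.to_numpy().mean()
    assert cv < 0.2


def test_moderated_variance_matches_independent_shrinkage_formula():
    """20-gene fixture: hyperparameters and posterior variances recomputed
    with an independent root-finding implementation of the moment fit."""
    rng = np.random.default_rng(5)
    n, p = 6, 4
    genes = pd.Index([f"g{i}" for i in range(20)], name="gene")
    cols = [f"s{i}" for i in range(n)]
    X = np.column_stack([np.ones(n), np.eye(n)[:, :2],
                         [1, 0, 1, 0, 1, 0]])
    y = pd.DataFrame(rng.normal(5, 1, (20, n)), index=genes, columns=cols)
    w = pd.DataFrame(rng.uniform(0.5, 2.0, (20, n)), index=genes,
                     columns=cols)
    design = DesignSpec(matrix=X, reduced=X[:, :3], condition_index=3,
                        sample_ids=pd.Index(cols),
                        condition=pd.Series([1, 0, 1, 0, 1, 0], index=cols))
    res = moderated_t_test(y, w, design)

    # independent oracle
    d = n - p
    s2 = []
    for g in genes:
        W = np.diag(w.loc[g])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y.loc[g])
        r = y.loc[g] - X @ beta
        s2.append(float(r @ W @ r) / d)
    s2 = np.array(s2)
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    evar = e.var(ddof=1) - special.polygamma(1, d / 2)
    assert evar > 0  # fixture has genuine spread
    d0 = 2 * optimize.brentq(
        lambda x: special.polygamma(1, x) - evar, 1e-3, 1e6)
    s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    post = (d0 * s0 + d * s2) / (d0 + d)
    assert np.allclose(res["s2_post"], post, rtol=1e-5)
    assert res["prior_df"].iloc[0] == pytest.approx(d0, rel=1e-4)


def test_moderation_limits():
    """Posterior variance always lies between s^2 and the prior variance."""
    cfg = SimConfig(seed=31, n_genes=200, timepoints=(18,),
                    n_replicates_per_tissue=3)
    cm, _ = synthio.simulate_rnaseq_counts(cfg)
    sub = filter_expressed(cm)
    design = DesignSpec.from_samples(sub.samples)
    logcpm, w = voom_transform(sub, design)
    res = moderated_t_test(logcpm, w, design)
    s0 = res["prior_var"].iloc[0]
    lo = np.minimum(res["s2_post"], s0)
    hi = np.maximum(res["s2_post"], s0)
    assert ((res["s2_post"] >= lo - 1e-12) & (res["s2_post"] <= hi + 1e-12)).all()


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def _bh_brute(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        vals = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(vals))
    return adj


def test_bh_hand_examples():
    assert bh_adjust([1.0]).tolist() == [1.0]
    assert np.allclose(bh_adjust([0.01, 0.02, 0.05]), [0.03, 0.03, 0.05])


def test_bh_ties_equal():
    out = bh_adjust([0.02, 0.02, 0.5])
    assert out[0] == out[1]


def test_bh_nan_passthrough_and_range_error():
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and np.isfinite(out[0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                min_size=1, max_size=50))
def test_bh_matches_brute_force(p):
    assert np.allclose(bh_adjust(p), _bh_brute(p))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _fake_results(genes, p_nb, p_lm, fc_nb, fc_lm):
    nb = pd.DataFrame({"log2fc": fc_nb, "dispersion": 0.1, "lr_stat": 1.0,
                       "p_nb": p_nb, "converged": True}, index=genes)
    lm = pd.DataFrame({"coef": fc_lm, "p_lm": p_lm}, index=genes)
    return nb, lm


def _uniform_tpm(genes, value_al=5.0, value_st=5.0):
    from aleuro.expression import TpmTable
    cols = pd.MultiIndex.from_tuples([("AL", 18), ("ST", 18)],
                                     names=["tissue", "timepoint"])
    mt = pd.DataFrame({("AL", 18): value_al, ("ST", 18): value_st},
                      index=genes)
    mt.columns = cols
    t = TpmTable(tpm=mt.copy(), samples=pd.DataFrame())
    t.mean_tpm, t.expressed = mt, mt > 0
    return t


def test_consensus_requires_both_paths():
    genes = pd.Index(["a", "b"], name="gene")
    nb, lm = _fake_results(genes, [1e-6, 1e-6], [1e-6, 0.9],
                           [3.0, 3.0], [3.0, 3.0])
    rec = call_consensus_degs(nb, lm, _uniform_tpm(genes), 18)
    assert bool(rec.loc["a", "consensus"])
    assert not bool(rec.loc["b", "consensus"])


def test_consensus_requires_fold_and_sign():
    genes = pd.Index(["small_fc", "sign_flip"], name="gene")
    nb, lm = _fake_results(genes, [1e-6, 1e-6], [1e-6, 1e-6],
                           [0.5, 3.0], [0.5, -3.0])
    rec = call_consensus_degs(nb, lm, _uniform_tpm(genes), 18)
    assert not rec["consensus"].any()


def test_zero_tpm_elimination():
    genes = pd.Index(["kept", "dropped"], name="gene")
    nb, lm = _fake_results(genes, [1e-6] * 2, [1e-6] * 2,
                           [3.0, 3.0], [3.0, 3.0])
    tpm = _uniform_tpm(genes, value_al=pd.Series([5.0, 5.0], index=genes),
                       value_st=pd.Series([5.0, 0.0], index=genes))
    rec = call_consensus_degs(nb, lm, tpm, 18)
    assert bool(rec.loc["dropped", "eliminated_zero_tpm"])
    assert not bool(rec.loc["dropped", "deg"])
    assert bool(rec.loc["kept", "deg"])


def test_gene_set_mismatch_errors():
    nb, lm = _fake_results(pd.Index(["a"], name="gene"),
                           [0.5], [0.5], [1.0], [1.0])
    lm2 = lm.copy()
    lm2.index = pd.Index(["zzz"], name="gene")
    with pytest.raises(ValueError, match="different gene sets"):
        call_consensus_degs(nb, lm2, _uniform_tpm(nb.index), 18)


def test_planted_truth_recovery_and_subset_invariant():
    """Final DEG list: empirical FDR <= 0.10, sensitivity >= 0.5, and the
    consensus set is a subset of each path's significant set."""
    cfg = SimConfig(seed=3, n_genes=2000, de_fraction=0.1,
                    log2fc_effect=2.0, nb_dispersion=0.1,
                    timepoints=(18,), n_replicates_per_tissue=3)
    cm, truth = synthio.simulate_rnaseq_counts(cfg)
    tpm = summarize_expression(compute_tpm(cm))
    rec = run_deg(cm, 18, tpm=tpm)
    called = set(rec.index[rec["deg"]])
    tp = len(called & set(truth.de_genes))
    fdr = (len(called) - tp) / max(len(called), 1)
    sens = tp / len(truth.de_genes)
    assert fdr <= 0.10
    assert sens >= 0.5
    sig_nb = set(rec.index[rec["fdr_nb"] <= 0.05])
    sig_lm = set(rec.index[rec["fdr_lm"] <= 0.05])
    cons = set(rec.index[rec["consensus"]])
    assert cons <= sig_nb and cons <= sig_lm
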