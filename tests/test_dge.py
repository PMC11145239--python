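"""Precision-weighted moderated differential expression.

Oracles: closed-form weighted normal equations for the per-gene fits, direct
formula evaluation for the empirical-Bayes shrinkage, statsmodels for BH,
and Bioconductor limma-voom (via Rscript) for the whole chain.
"""

import dataclasses
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from vascsig import (
    DataError,
    DesignInfo,
    ModelError,
    bh_adjust,
    build_cohort,
    assign_vascular_groups,
    ebayes_moderate,
    fit_moderated,
    log2cpm,
    run_dge,
    simulate_cohort,
    voom_transform,
)
from vascsig.dge import GeneFits

from conftest import toy_counts


def _nb_counts(rng, n_genes=80, n_samples=16, mean_range=(2, 2000)):
    mu = rng.uniform(*mean_range, size=(n_genes, 1)) * np.ones((1, n_samples))
    r = 5.0
    return toy_counts(rng.negative_binomial(r, r / (r + mu)))


def _design(n, n_group1, age=None):
    group = np.zeros(n)
    group[:n_group1] = 1.0
    return DesignInfo(group=group, age=age)


# ---------------------------------------------------------------- log2cpm


def test_log2cpm_formula():
    cm = toy_counts([[0, 10], [4, 10]])
    expr = log2cpm(cm, prior_count=0.5)
    lib = np.array([4.0, 20.0])
    expected = np.log2((cm.counts + 0.5) / (lib + 1.0) * 1e6)
    np.testing.assert_allclose(expr.values, expected)


# ------------------------------------------------------------------ voom


def test_identical_genes_get_identical_weights(rng):
    base = rng.integers(5, 50, size=(1, 12))
    counts = np.vstack([base, base, rng.integers(5, 5000, size=(18, 12))])
    fit = voom_transform(toy_counts(counts), _design(12, 6))
    np.testing.assert_allclose(fit.weights[0], fit.weights[1])


def test_weights_increase_with_expression(rng):
    counts = _nb_counts(rng, n_genes=120)
    fit = voom_transform(counts, _design(16, 8))
    assert np.isfinite(fit.weights).all() and (fit.weights > 0).all()
    avg = fit.logcpm.values.mean(axis=1)
    rho = stats.spearmanr(avg, fit.weights.mean(axis=1)).statistic
    assert rho > 0


def test_constant_gene_keeps_finite_weights(rng):
    counts = _nb_counts(rng, n_genes=40)
    counts.counts[0, :] = 7  # zero residual variance
    fit = voom_transform(counts, _design(16, 8))
    assert np.isfinite(fit.weights[0]).all() and (fit.weights[0] > 0).all()


def test_collinear_design_rejected():
    group = np.array([1.0, 1, 0, 0, 1, 1])
    with pytest.raises(ModelError):
        DesignInfo(group=group, age=group * 2).matrix


# ----------------------------------------------------------- WLS fitting


def test_wls_matches_normal_equations_oracle(rng):
    counts = _nb_counts(rng, n_genes=30, n_samples=6)
    age = rng.uniform(40, 80, 6)
    design = _design(6, 3, age=age)
    fit = voom_transform(counts, design)
    fits = fit_moderated(fit, design)
    X = design.matrix
    for g in range(counts.n_genes):
        W = np.diag(fit.weights[g])
        y = fit.logcpm.values[g]
        A = X.T @ W @ X
        beta = np.linalg.solve(A, X.T @ W @ y)
        resid = y - X @ beta
        s2 = (fit.weights[g] * resid**2).sum() / (6 - 3)
        se = np.sqrt(s2 * np.linalg.inv(A)[1, 1])
        assert fits.coef[g] == pytest.approx(beta[1], rel=1e-8)
        assert fits.stderr[g] == pytest.approx(se, rel=1e-8)
        assert fits.sigma2[g] == pytest.approx(s2, rel=1e-8)


def test_no_effect_gene_has_near_zero_coef():
    counts = toy_counts(np.tile([[100, 100, 100, 100, 100, 100]], (20, 1)))
    counts.counts[1:] = np.arange(20, 2020, 100)[1:, None]
    design = _design(6, 3)
    fit = voom_transform(counts, design)
    fits = fit_moderated(fit, design)
    assert fits.coef[0] == pytest.approx(0.0, abs=1e-10)


def test_rescaling_weights_leaves_coef_and_stderr_unchanged(rng):
    counts = _nb_counts(rng, n_genes=25, n_samples=10)
    design = _design(10, 5)
    fit = voom_transform(counts, design)
    fits1 = fit_moderated(fit, design)
    fit2 = dataclasses.replace(fit, weights=fit.weights * 2.0)
    fits2 = fit_moderated(fit2, design)
    np.testing.assert_allclose(fits1.coef, fits2.coef, rtol=1e-10)
    np.testing.assert_allclose(fits1.stderr, fits2.stderr, rtol=1e-10)


# -------------------------------------------------------- empirical Bayes


def _fake_fits(coef, sigma2, df, unscaled=1.0):
    coef = np.asarray(coef, float)
    s2 = np.asarray(sigma2, float)
    un = np.full_like(coef, unscaled)
    return GeneFits(
        gene_ids=[f"g{i}" for i in range(len(coef))],
        coef=coef,
        stderr=np.sqrt(s2) * un,
        stdev_unscaled=un,
        sigma2=s2,
        df_resid=df,
        avg_log2cpm=np.zeros_like(coef),
    )


def test_identical_variances_hit_full_shrinkage_limit():
    fits = _fake_fits([1.0, 2.0, 3.0], [0.5, 0.5, 0.5], df=4)
    eb = ebayes_moderate(fits)
    assert np.isinf(eb.df_prior)
    np.testing.assert_allclose(eb.var_post, eb.var_prior)
    np.testing.assert_allclose(eb.var_post, 0.5, rtol=1e-6)


def test_moderated_variance_betweenness_and_formula(rng):
    # heterogeneous true variances (finite prior df), chi-square sampling noise
    true_var = 0.8 * 4 / rng.chisquare(4, size=50)
    s2 = true_var * rng.chisquare(6, size=50) / 6
    fits = _fake_fits(rng.normal(size=50), s2, df=6)
    eb = ebayes_moderate(fits)
    d0, s02 = eb.df_prior, eb.var_prior
    assert np.isfinite(d0) and d0 > 0
    expected_post = (d0 * s02 + 6 * s2) / (d0 + 6)
    np.testing.assert_allclose(eb.var_post, expected_post, rtol=1e-10)
    lo = np.minimum(s2, s02)
    hi = np.maximum(s2, s02)
    assert ((eb.var_post >= lo - 1e-12) & (eb.var_post <= hi + 1e-12)).all()
    # moderated t recomputed from the definition
    np.testing.assert_allclose(
        eb.moderated_t, fits.coef / np.sqrt(eb.var_post), rtol=1e-10
    )
    np.testing.assert_allclose(
        eb.p_value, 2 * stats.t.sf(np.abs(eb.moderated_t), 6 + d0), rtol=1e-10
    )


def test_prior_estimates_match_moment_equations(rng):
    """d0, s0^2 satisfy the log-variance moment conditions they were fit to."""
    true_var = 2.0 * 6 / rng.chisquare(6, size=400)
    s2 = true_var * rng.chisquare(5, size=400) / 5
    fits = _fake_fits(np.zeros(400), s2, df=5)
    eb = ebayes_moderate(fits)
    e = np.log(s2) - special.digamma(2.5) + np.log(2.5)
    assert special.polygamma(1, eb.df_prior / 2) == pytest.approx(
        np.var(e, ddof=1) - special.polygamma(1, 2.5), rel=1e-6
    )


# ----------------------------------------------------------------- BH FDR


def test_bh_hand_examples():
    np.testing.assert_allclose(bh_adjust([0.03]), [0.03])
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(1e-6, 1, size=200)
    q = bh_adjust(p)
    _, q_sm, *_ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, rtol=1e-12)


def test_bh_preserves_p_order(rng):
    p = rng.uniform(1e-6, 1, size=57)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(DataError):
        bh_adjust([0.0, 0.5])
    with pytest.raises(DataError):
        bh_adjust([0.5, 1.2])


# ------------------------------------------------------------- run_dge


def _contrast_cohort(seed=5, logfc=(2.5, 2.5), n_genes=150):
    from vascsig import SyntheticConfig

    cfg = SyntheticConfig(
        n_samples=40,
        n_mri=8,
        n_genes=n_genes,
        n_signature_genes=6,
        signature_logfc_range=logfc,
        frac_hv=1.0,
        seed=seed,
    )
    counts, ann, clin, truth = simulate_cohort(cfg)
    cohort = assign_vascular_groups(build_cohort(counts, clin, ann))
    return cohort, truth


def test_sign_convention_positive_means_higher_in_hv():
    cohort, truth = _contrast_cohort()
    table, _ = run_dge(cohort, alpha=0.01)
    boosted = cohort.counts.counts.copy()
    hv = {
        p.patient_id for p in cohort.patients if p.vascular_group == "HV"
    }
    cols = [i for i, s in enumerate(cohort.counts.sample_ids) if s in hv]
    boosted[0, cols] *= 4
    from vascsig import CountMatrix

    cohort.counts = CountMatrix(
        gene_ids=cohort.counts.gene_ids,
        sample_ids=cohort.counts.sample_ids,
        counts=boosted,
    )
    table2, _ = run_dge(cohort, alpha=0.01)
    g0 = cohort.counts.gene_ids[0]
    before = table.set_index("gene_id").loc[g0, "logFC"]
    after = table2.set_index("gene_id").loc[g0, "logFC"]
    assert after > before


def test_sample_order_permutation_leaves_results_invariant():
    cohort, _ = _contrast_cohort(seed=9)
    table1, _ = run_dge(cohort)
    cohort2, _ = _contrast_cohort(seed=9)
    rng = np.random.default_rng(3)
    counts = cohort2.counts
    perm = rng.permutation(counts.n_samples)
    cohort2.counts = counts.subset_samples([counts.sample_ids[i] for i in perm])
    table2, _ = run_dge(cohort2)
    merged = table1.merge(table2, on="gene_id", suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["logFC_a"], merged["logFC_b"], rtol=1e-9)
    np.testing.assert_allclose(merged["q_value_a"], merged["q_value_b"], rtol=1e-9)


def test_signature_directions_match_logfc_sign():
    cohort, _ = _contrast_cohort(seed=13)
    table, signature = run_dge(cohort, alpha=0.05)
    lfc = table.set_index("gene_id")["logFC"]
    for gid, direction in signature.entries:
        assert (lfc[gid] > 0) == (direction == "over")


# ------------------------------------------------- limma-voom cross-check

_R_SCRIPT = textwrap.dedent(
    """
    suppressMessages(library(limma))
    suppressMessages(library(edgeR))
    counts <- as.matrix(read.delim("{counts}", row.names = 1, check.names = FALSE))
    design <- as.matrix(read.delim("{design}", check.names = FALSE))
    v <- voom(counts, design, span = 0.5)
    fit <- eBayes(lmFit(v, design))
    out <- data.frame(
      gene_id = rownames(counts),
      logFC = fit$coefficients[, "group"],
      t = fit$t[, "group"],
      p = fit$p.value[, "group"]
    )
    write.table(out, "{out}", sep = "\\t", row.names = FALSE, quote = FALSE)
    """
)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_pipeline_agrees_with_bioconductor_limma_voom(tmp_path, rng):
    raw = _nb_counts(rng, n_genes=200, n_samples=30).counts
    # plant a few real effects so both tools face signal and null genes
    raw[:5, :6] *= 3
    counts = toy_counts(raw)  # library sizes computed on the final counts
    age = rng.uniform(40, 80, 30)
    design = _design(30, 6, age=age)

    counts.to_dataframe().to_csv(tmp_path / "counts.tsv", sep="\t")
    pd.DataFrame(
        {"intercept": 1.0, "group": design.group, "age": design.age}
    ).to_csv(tmp_path / "design.tsv", sep="\t", index=False)
    script = _R_SCRIPT.format(
        counts=tmp_path / "counts.tsv",
        design=tmp_path / "design.tsv",
        out=tmp_path / "limma.tsv",
    )
    (tmp_path / "run.R").write_text(script)
    subprocess.run(
        ["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True
    )
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")

    fit = voom_transform(counts, design)
    fits = fit_moderated(fit, design)
    eb = ebayes_moderate(fits)

    np.testing.assert_allclose(fits.coef, ref["logFC"], atol=0.02)
    r = np.corrcoef(eb.moderated_t, ref["t"])[0, 1]
    assert r > 0.995
    # same genes called at a lenient threshold
    ours = set(np.array(fits.gene_ids)[bh_adjust(eb.p_value) < 0.05])
    theirs = set(ref.loc[bh_adjust(ref["p"].to_numpy()) < 0.05, "gene_id"])
    assert ours == theirs
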