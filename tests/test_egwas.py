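"""Mixed-model association: score test, two-level FDR, pruning, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodeqtl import (
    GenotypeMatrix,
    KinshipMatrix,
    build_design,
    chromosome_enrichment,
    classify_local_distant,
    effect_sd_ratio,
    eigendecompose_kinship,
    fit_polygenic_null,
    prune_to_eqtl_snps,
    run_egwas,
    score_test,
    snp_regulation_summary,
    two_level_fdr,
)
from bloodeqtl.egwas import _bh_threshold
from bloodeqtl.preprocess import ExpressionMatrix

from conftest import toy_genotypes


def identity_kinship(samples):
    return KinshipMatrix(
        pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples),
        source_snp_count=0,
    )


def ols_score_test_oracle(y, g):
    """Closed-form score test for a slope in simple linear regression.

    Residual variance estimated under the intercept-only null with the
    REML (n-1) denominator; the statistic is the squared score over its
    information, referred to chi-square with 1 df.
    """
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    yc = y - y.mean()
    gc = g - g.mean()
    sigma2 = yc @ yc / (len(y) - 1)
    T = (gc @ yc) ** 2 / (sigma2 * (gc @ gc))
    return stats.chi2.sf(T, df=1)


def test_score_test_equals_ols_score_with_identity_kinship():
    rng = np.random.default_rng(0)
    n = 120
    samples = [f"s{i}" for i in range(n)]
    K = identity_kinship(samples)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=samples)
    for rep in range(20):
        y = pd.Series(rng.standard_normal(n), index=samples)
        g = rng.binomial(2, 0.4, size=n).astype(float)
        model = fit_polygenic_null(y, X, K)
        _, _, p = score_test(model, g)
        expected = ols_score_test_oracle(y, g)
        assert p == pytest.approx(expected, rel=1e-9)


def test_identity_kinship_total_variance_matches_ols():
    rng = np.random.default_rng(1)
    n = 80
    samples = [f"s{i}" for i in range(n)]
    y = pd.Series(rng.standard_normal(n) * 2.0, index=samples)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=samples)
    model = fit_polygenic_null(y, X, identity_kinship(samples))
    # with K = I the split g/e is unidentifiable but the total matches OLS
    assert model.sigma2_total == pytest.approx(y.var(ddof=1), rel=1e-6)


def test_zero_noise_fit_hits_variance_floor():
    n = 30
    samples = [f"s{i}" for i in range(n)]
    X = build_design(pd.DataFrame({"sex": ["M", "F"] * 15}, index=samples))
    y = pd.Series(X.to_numpy() @ np.array([3.0, -1.0]), index=samples)
    model = fit_polygenic_null(y, X, identity_kinship(samples))
    assert model.sigma2_total <= 1e-10
    fitted = X.to_numpy() @ model.fixed_effects.to_numpy()
    assert fitted == pytest.approx(y.to_numpy(), abs=1e-6)


def test_singular_design_names_collinear_column():
    n = 20
    samples = [f"s{i}" for i in range(n)]
    X = pd.DataFrame(
        {"intercept": np.ones(n), "dup": np.ones(n)}, index=samples
    )
    y = pd.Series(np.random.default_rng(2).standard_normal(n), index=samples)
    with pytest.raises(ValueError, match="singular design"):
        fit_polygenic_null(y, X, identity_kinship(samples))


def test_monomorphic_snp_returns_nan_not_exception():
    n = 40
    samples = [f"s{i}" for i in range(n)]
    y = pd.Series(np.random.default_rng(3).standard_normal(n), index=samples)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=samples)
    model = fit_polygenic_null(y, X, identity_kinship(samples))
    beta, T, p = score_test(model, np.ones(n))
    assert np.isnan(beta) and np.isnan(p)


def test_missing_dosages_use_complete_subset():
    rng = np.random.default_rng(4)
    n = 100
    samples = [f"s{i}" for i in range(n)]
    g = rng.binomial(2, 0.5, size=n).astype(float)
    y = pd.Series(0.8 * g + rng.standard_normal(n), index=samples)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=samples)
    model = fit_polygenic_null(y, X, identity_kinship(samples))
    g_missing = g.copy()
    g_missing[:10] = np.nan
    _, _, p_missing = score_test(model, g_missing)
    expected = ols_score_test_oracle(y[10:], g[10:])
    assert p_missing == pytest.approx(expected, rel=1e-6)


def test_heritability_recovered_in_structured_cohort():
    from bloodeqtl import SimulationConfig, design_architecture, \
        simulate_expression, simulate_genotypes
    from bloodeqtl.qc import compute_genomic_kinship

    config = SimulationConfig(n_sires=10, progeny_per_sire=40, n_snps=300,
                              n_probes=4, n_chromosomes=3, n_cis_effects=0,
                              n_trans_effects=0, h2_polygenic=0.6,
                              batch_effect_sd_units=0.0,
                              sex_effect_sd_units=0.0, seed=21)
    geno, _ = simulate_genotypes(config)
    arch = design_architecture(geno, config)
    expr, covars = simulate_expression(geno, arch, config)
    K = compute_genomic_kinship(geno)
    X = build_design(covars[["sex"]])
    h2s = []
    for probe in expr.values.columns[:4]:
        model = fit_polygenic_null(expr.values[probe], X, K)
        h2s.append(model.h2)
    assert np.mean(h2s) == pytest.approx(0.6, abs=0.15)


def _toy_run(n=60, seed=5, n_snps=6, n_probes=3, beta=None):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    G = rng.binomial(2, 0.4, size=(n, n_snps)).astype(float)
    geno = toy_genotypes(G)
    geno.dosages.index = samples
    geno.dosages.index.name = None
    geno = GenotypeMatrix(
        pd.DataFrame(G, index=samples, columns=geno.dosages.columns),
        geno.snp_map,
    )
    values = rng.standard_normal((n, n_probes))
    if beta:
        for (j_probe, j_snp, b) in beta:
            values[:, j_probe] += b * G[:, j_snp]
    probes = [f"p{j}" for j in range(n_probes)]
    ann = pd.DataFrame(
        {"chromosome": "1", "start_bp": 1000, "strand": "+",
         "gene_symbol": [f"g{j}" for j in range(n_probes)], "sense": True},
        index=pd.Index(probes, name="probe_id"),
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=samples, columns=probes),
        probe_annotation=ann,
    )
    covars = pd.DataFrame({"batch": ["a", "b"] * (n // 2)}, index=samples)
    return expr, geno, covars, identity_kinship(samples)


def test_run_egwas_cardinality_and_permutation_invariance():
    expr, geno, covars, K = _toy_run(n_probes=5, n_snps=10)
    records = run_egwas(expr, geno, covars, K)
    assert len(records) == 50
    # permute samples consistently everywhere: identical p-values
    perm = np.random.default_rng(6).permutation(expr.values.index)
    expr2 = ExpressionMatrix(expr.values.loc[perm], expr.probe_annotation)
    geno2 = GenotypeMatrix(geno.dosages.loc[perm], geno.snp_map)
    K2 = KinshipMatrix(K.values.loc[perm, perm], 0)
    records2 = run_egwas(expr2, geno2, covars.loc[perm], K2)
    merged = records.merge(records2, on=["probe_id", "snp_id"])
    assert merged["p_value_x"].to_numpy() == pytest.approx(
        merged["p_value_y"].to_numpy(), rel=1e-8
    )


def test_run_egwas_rejects_sample_mismatch():
    expr, geno, covars, K = _toy_run()
    covars_bad = covars.iloc[:-1]
    with pytest.raises(ValueError, match="sample mismatch"):
        run_egwas(expr, geno, covars_bad, K)


def hand_bh(pvals, alpha):
    """Step-up BH by hand: indices of rejected hypotheses."""
    order = np.argsort(pvals)
    m = len(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_max = rank
    return set(order[:k_max])


def test_two_level_fdr_matches_hand_bh_oracle():
    records = pd.DataFrame(
        {"probe_id": ["A"] * 3 + ["B"] * 3,
         "snp_id": ["v0", "v1", "v2"] * 2,
         "beta_snp": 0.0, "score_statistic": 0.0,
         "p_value": [0.001, 0.02, 0.9, 0.5, 0.6, 0.7]}
    )
    out, thresholds = two_level_fdr(records, 0.05, 0.05)
    p = records["p_value"].to_numpy()
    rej_A = hand_bh(p[:3], 0.05)
    rej_global = hand_bh(p, 0.05)
    expected_sig = {
        i for i in range(6)
        if (i in rej_global)
        and ((i % 3) in (rej_A if i < 3 else hand_bh(p[3:], 0.05)))
    }
    got_sig = set(np.nonzero(out["is_significant"].to_numpy())[0])
    assert got_sig == expected_sig
    # q-values match statsmodels BH applied per group
    from statsmodels.stats.multitest import multipletests

    q_A = multipletests(p[:3], method="fdr_bh")[1]
    assert out.loc[:2, "q_probe"].to_numpy() == pytest.approx(q_A)


def test_two_level_fdr_all_ones_nothing_significant():
    records = pd.DataFrame(
        {"probe_id": ["A"] * 4, "snp_id": list("wxyz"),
         "beta_snp": 0.0, "score_statistic": 0.0, "p_value": [1.0] * 4}
    )
    out, thresholds = two_level_fdr(records)
    assert not out["is_significant"].any()
    assert thresholds["global"] == -np.inf


def test_bh_threshold_is_max_rejected_p():
    p = np.array([0.001, 0.012, 0.02, 0.8])
    # BH at 0.05: crit 0.0125, 0.025, 0.0375, 0.05 -> reject first three
    assert _bh_threshold(p, 0.05) == 0.02


def _pruning_setup(positions, dosage_cols, beta_cols, n=150, seed=7,
                   chroms=None):
    """One probe driven by the listed SNP columns; returns pruning inputs."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    m = len(positions)
    G = np.column_stack(dosage_cols).astype(float)
    assert G.shape == (n, m)
    geno = toy_genotypes(G, chroms=chroms or ["1"] * m, positions=positions)
    geno = GenotypeMatrix(
        pd.DataFrame(G, index=samples, columns=geno.dosages.columns),
        geno.snp_map,
    )
    y = rng.standard_normal(n) * 0.5
    for j, b in beta_cols:
        y = y + b * G[:, j]
    ann = pd.DataFrame(
        {"chromosome": "1", "start_bp": positions[0], "strand": "+",
         "gene_symbol": "g0", "sense": True},
        index=pd.Index(["p0"], name="probe_id"),
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame({"p0": y}, index=samples), probe_annotation=ann
    )
    covars = pd.DataFrame({"batch": ["a"] * n}, index=samples)
    K = identity_kinship(samples)
    records = run_egwas(expr, geno, covars, K)
    records, thresholds = two_level_fdr(records)
    sig = records[records["is_significant"]]
    return sig, geno, expr, covars, K, thresholds


def test_perfect_ld_pair_collapses_to_single_lead():
    rng = np.random.default_rng(8)
    g = rng.binomial(2, 0.5, size=150).astype(float)
    sig, geno, expr, covars, K, thr = _pruning_setup(
        positions=[1_000_000, 1_100_000], dosage_cols=[g, g],
        beta_cols=[(0, 1.0)],
    )
    assert len(sig) == 2
    eqtl = prune_to_eqtl_snps(sig, geno, expr, covars, K, thr)
    assert len(eqtl) == 1
    # identical p-values: tie broken by smaller genomic position
    assert eqtl.iloc[0]["lead_snp_id"] == "v0"
    assert eqtl.iloc[0]["n_pruned"] == 1


def test_snps_beyond_window_never_merge():
    rng = np.random.default_rng(9)
    g = rng.binomial(2, 0.5, size=150).astype(float)
    sig, geno, expr, covars, K, thr = _pruning_setup(
        positions=[1_000_000, 7_000_000], dosage_cols=[g, g],
        beta_cols=[(0, 1.0)],
    )
    eqtl = prune_to_eqtl_snps(sig, geno, expr, covars, K, thr)
    # 6 Mb apart: outside the 5-Mb window, both survive even in perfect LD
    assert len(eqtl) == 2


def test_independent_causal_snps_both_retained():
    rng = np.random.default_rng(10)
    g1 = rng.binomial(2, 0.5, size=200).astype(float)
    g2 = rng.binomial(2, 0.5, size=200).astype(float)
    sig, geno, expr, covars, K, thr = _pruning_setup(
        positions=[1_000_000, 2_000_000], dosage_cols=[g1, g2],
        beta_cols=[(0, 1.0), (1, 1.0)], n=200,
    )
    eqtl = prune_to_eqtl_snps(sig, geno, expr, covars, K, thr)
    assert set(eqtl["lead_snp_id"]) == {"v0", "v1"}


def test_pruning_invariant_to_record_order():
    rng = np.random.default_rng(11)
    g1 = rng.binomial(2, 0.5, size=150).astype(float)
    g2 = np.clip(g1 + rng.binomial(1, 0.1, size=150) - rng.binomial(1, 0.1, size=150), 0, 2)
    sig, geno, expr, covars, K, thr = _pruning_setup(
        positions=[1_000_000, 1_500_000], dosage_cols=[g1, g2],
        beta_cols=[(0, 1.0)],
    )
    if len(sig) < 2:
        pytest.skip("fixture did not yield two significant SNPs")
    e1 = prune_to_eqtl_snps(sig, geno, expr, covars, K, thr)
    e2 = prune_to_eqtl_snps(sig.iloc[::-1], geno, expr, covars, K, thr)
    pd.testing.assert_frame_equal(
        e1.reset_index(drop=True), e2.reset_index(drop=True)
    )


def test_lead_p_not_larger_than_pruned_ps():
    rng = np.random.default_rng(12)
    base = rng.binomial(2, 0.5, size=200).astype(float)
    cols = [base]
    for _ in range(3):  # noisy copies in LD
        noise = rng.binomial(1, 0.15, size=200) - rng.binomial(1, 0.15, size=200)
        cols.append(np.clip(base + noise, 0, 2))
    sig, geno, expr, covars, K, thr = _pruning_setup(
        positions=[1_000_000, 1_200_000, 1_400_000, 1_600_000],
        dosage_cols=cols, beta_cols=[(0, 1.0)], n=200,
    )
    eqtl = prune_to_eqtl_snps(sig, geno, expr, covars, K, thr)
    sig_p = sig.set_index("snp_id")["p_value"]
    for _, row in eqtl.iterrows():
        pruned = sig_p.drop(index=eqtl["lead_snp_id"])
        near = [
            s for s in pruned.index
            if abs(geno.snp_map.loc[s, "position_bp"] - row["position_bp"]) <= 5_000_000
        ]
        assert all(row["p_lead"] <= sig_p[s] for s in near)


def _classified(positions, probe_chrom, probe_start, snp_chroms):
    eqtl = pd.DataFrame(
        {"probe_id": "p0", "lead_snp_id": [f"v{i}" for i in range(len(positions))],
         "chromosome": snp_chroms, "position_bp": positions,
         "p_lead": 1e-8, "beta_lead": 1.0}
    )
    ann = pd.DataFrame(
        {"chromosome": [probe_chrom], "start_bp": [probe_start]},
        index=pd.Index(["p0"], name="probe_id"),
    )
    return classify_local_distant(eqtl, ann)


def test_local_distant_classification_boundaries():
    out = _classified(
        positions=[5_000_000, 5_000_000, 4_000_000, 6_000_001],
        probe_chrom="1", probe_start=5_000_000,
        snp_chroms=["1", "2", "1", "1"],
    )
    assert out["regulation_class"].tolist() == [
        "local",     # same position
        "distant",   # other chromosome, regardless of coordinates
        "local",     # exactly 1 Mb away: inclusive boundary
        "distant",   # 1,000,001 bp away
    ]


def test_unmapped_probe_gets_na_class():
    eqtl = pd.DataFrame(
        {"probe_id": ["p0"], "lead_snp_id": ["v0"], "chromosome": ["1"],
         "position_bp": [100], "p_lead": [1e-9], "beta_lead": [1.0]}
    )
    ann = pd.DataFrame(
        {"chromosome": [None], "start_bp": [None]},
        index=pd.Index(["p0"], name="probe_id"),
    )
    out = classify_local_distant(eqtl, ann)
    assert out["regulation_class"].isna().all()


def test_snp_summary_both_label():
    classified = pd.DataFrame(
        {"lead_snp_id": ["v0", "v0", "v1"],
         "regulation_class": ["local", "distant", "local"]}
    )
    summary = snp_regulation_summary(classified)
    assert summary["v0"] == "both"
    assert summary["v1"] == "local"


def test_effect_sd_ratio_values():
    assert effect_sd_ratio(1.5, [0.0, 1.5]) == pytest.approx(
        1.5 / np.std([0.0, 1.5], ddof=1)
    )
    assert effect_sd_ratio(0.0, [1.0, 2.0, 3.0]) == 0.0
    vals = np.array([0.0, 0.75, 1.5])  # SD = 0.75
    assert effect_sd_ratio(1.5, vals) == pytest.approx(2.0)
    assert np.isnan(effect_sd_ratio(1.0, [2.0, 2.0]))


def test_chromosome_enrichment_matches_hypergeometric_tail():
    chrom = pd.Series(
        ["1"] * 100 + ["2"] * 900,
        index=[f"v{i}" for i in range(1000)],
    )
    features = [f"v{i}" for i in range(10)] + [f"v{i}" for i in range(100, 140)]
    out = chromosome_enrichment(features, chrom.index, chrom)
    row = out.set_index("chromosome").loc["1"]
    # one-sided Fisher == hypergeometric upper tail
    expected = stats.hypergeom.sf(10 - 1, 1000, 50, 100)
    assert row["fisher_p_enrichment"] == pytest.approx(expected, rel=1e-9)


def test_chromosome_enrichment_null_and_identity_cases():
    chrom = pd.Series(["1"] * 50 + ["2"] * 50, index=[f"v{i}" for i in range(100)])
    # feature set proportional on both chromosomes
    features = [f"v{i}" for i in range(10)] + [f"v{i}" for i in range(50, 60)]
    out = chromosome_enrichment(features, chrom.index, chrom).set_index("chromosome")
    assert (out["fisher_p_enrichment"] > 0.05).all()
    # feature set == background: odds ratio 1, p = 1
    out2 = chromosome_enrichment(chrom.index, chrom.index, chrom)
    assert (out2["fisher_p_enrichment"] == 1.0).all()


def test_chromosome_enrichment_requires_subset():
    chrom = pd.Series(["1", "2"], index=["a", "b"])
    with pytest.raises(ValueError, match="subset"):
        chromosome_enrichment(["c"], ["a", "b"], chrom)
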