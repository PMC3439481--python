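import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivarped import errors
from bivarped.hemodel import (TheModelSpec, fit_bivariate_the,
                              fit_univariate_the, genome_scan, genomic_lambda,
                              interaction_model, variance_explained, wald_test)
from bivarped.io import GenotypeMatrix, MarkerMeta, PedRecord
from bivarped.pedigree import build_pedigree, kinship
from bivarped.simulate import (SimulationConfig, gene_drop, simulate_dataset,
                               simulate_pedigrees, simulate_traits)


def _unrelated_cohort(n, seed):
    """n singleton families with iid bivariate traits and one SNP."""
    rng = np.random.default_rng(seed)
    recs = [PedRecord(f"F{i}", f"s{i}", None, None, "male") for i in range(n)]
    ped = build_pedigree(recs)
    phi = kinship(ped)
    ids = [r.individual_id for r in recs]
    snp = rng.binomial(2, 0.3, n).astype(float)
    Y = 0.3 * snp[:, None] + rng.multivariate_normal(
        [0, 0], [[1.0, 0.4], [0.4, 1.0]], size=n)
    traits = pd.DataFrame(Y, index=ids, columns=["t1", "t2"])
    design = pd.DataFrame({"snp": snp}, index=ids)
    return ped, phi, traits, design


def test_unrelated_fit_equals_closed_form_multivariate_ls():
    ped, phi, traits, design = _unrelated_cohort(200, seed=1)
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design),
                            phi, ped)
    X = np.column_stack([np.ones(200), design["snp"]])
    for k, t in enumerate(["t1", "t2"]):
        beta_ols = np.linalg.lstsq(X, traits[t].to_numpy(), rcond=None)[0]
        assert fit.coef(f"{t}:intercept") == pytest.approx(beta_ols[0], abs=1e-6)
        assert fit.coef(f"{t}:snp") == pytest.approx(beta_ols[1], abs=1e-6)
    # with no relatives 2*Phi = I: the polygenic component is unidentifiable
    # and is attributed entirely to the residual (floored to zero)
    assert np.allclose(fit.vc.sigma_g, 0.0, atol=1e-8)


def test_wald_single_coefficient_identity():
    ped, phi, traits, design = _unrelated_cohort(150, seed=2)
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design),
                            phi, ped)
    stat, df, p = wald_test(fit, ["t1:snp"])
    z = fit.coef("t1:snp") / fit.se("t1:snp")
    assert df == 1
    assert stat == pytest.approx(z * z, rel=1e-10)
    assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-8)


def test_wald_zero_coefficients():
    ped, phi, traits, design = _unrelated_cohort(150, seed=3)
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design),
                            phi, ped)
    fit.beta[:] = 0.0
    stat, df, p = wald_test(fit, ["t1:snp", "t2:snp"])
    assert stat == 0.0 and p == 1.0


def test_variance_component_recovery_sibships():
    cfg = SimulationConfig(seed=33, n_pedigrees=500, structure=("nuclear", 2),
                           n_markers=1, sigma_g=((0.5, 0.25), (0.25, 0.5)),
                           sigma_e=((0.5, 0.0), (0.0, 0.5)),
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    fit = fit_bivariate_the(TheModelSpec(traits=traits), phi, ped)
    h2 = fit.vc.heritability()
    assert np.all(np.abs(h2 - 0.5) < 0.1)
    assert fit.vc.genetic_correlation() == pytest.approx(0.5, abs=0.2)


def test_univariate_consistent_with_duplicated_trait():
    cfg = SimulationConfig(seed=34, n_pedigrees=200, structure=("nuclear", 2),
                           n_markers=1, causal_markers=[(0, 0.2, 0.2)],
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    t1 = pheno.set_index("subject_id")["trait1"]
    snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
    uni = fit_univariate_the(t1, snp.to_frame(), phi, ped)
    assert uni.df == 1 and uni.converged
    # duplicating the same trait in the bivariate machinery reproduces the
    # univariate effect estimate
    dup = pd.DataFrame({"a": t1, "b": t1})
    fit2 = fit_bivariate_the(
        TheModelSpec(traits=dup, fixed_effects=snp.to_frame(), vc_floor=1e-8),
        phi, ped)
    assert fit2.coef("a:snp") == pytest.approx(uni.beta[0], abs=1e-3)
    assert uni.beta[0] > 0  # generating effect sign recovered


def test_estimates_invariant_to_subject_permutation():
    cfg = SimulationConfig(seed=35, n_pedigrees=80, structure=("nuclear", 3),
                           n_markers=1, causal_markers=[(0, 0.3, 0.1)])
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
    fit1 = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=snp.to_frame()),
                             phi, ped)
    perm = np.random.default_rng(0).permutation(len(traits))
    fit2 = fit_bivariate_the(
        TheModelSpec(traits=traits.iloc[perm], fixed_effects=snp.to_frame().iloc[perm]),
        phi, ped)
    assert fit1.coef("trait1:snp") == pytest.approx(fit2.coef("trait1:snp"), abs=1e-8)
    assert np.allclose(fit1.vc.sigma_g, fit2.vc.sigma_g, atol=1e-8)


def test_interaction_pure_product_effect_detected():
    rng = np.random.default_rng(41)
    cfg = SimulationConfig(seed=41, n_pedigrees=250, structure=("nuclear", 2),
                           n_markers=2, maf_spectrum=[0.4, 0.4],
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    s1 = pd.Series(g.values[:, 0], index=g.subject_ids)
    s2 = pd.Series(g.values[:, 1], index=g.subject_ids)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]].copy()
    inter = (s1 * s2).reindex(traits.index)
    traits["trait1"] += 0.4 * inter
    traits["trait2"] += 0.4 * inter
    table = interaction_model(s1, s2, traits, phi, ped)
    row = table[table["term"] == "snp1_x_snp2"].iloc[0]
    assert row["p_biv"] < 0.01
    assert row["beta_biv_t1"] == pytest.approx(0.4, abs=0.15)
    # main-effect rows carry no generating signal beyond leakage via LD ~ 0
    assert table[table["term"] == "snp1"]["p_biv"].iloc[0] > 1e-4


def test_interaction_no_joint_carriers():
    rng = np.random.default_rng(42)
    n = 200
    recs = [PedRecord(f"F{i}", f"s{i}", None, None, "male") for i in range(n)]
    ped = build_pedigree(recs)
    phi = kinship(ped)
    ids = [r.individual_id for r in recs]
    # carriers of snp1 and snp2 are disjoint -> product term identically 0
    s1 = np.zeros(n); s1[:40] = 1.0
    s2 = np.zeros(n); s2[60:100] = 1.0
    traits = pd.DataFrame(rng.normal(size=(n, 2)), index=ids, columns=["t1", "t2"])
    table = interaction_model(pd.Series(s1, index=ids), pd.Series(s2, index=ids),
                              traits, phi, ped)
    row = table[table["term"] == "snp1_x_snp2"].iloc[0]
    assert row["beta_biv_t1"] == pytest.approx(0.0, abs=1e-10)
    assert row["p_biv"] == pytest.approx(1.0)


def test_interaction_collinear_snps_warn():
    ped, phi, traits, design = _unrelated_cohort(200, seed=5)
    s1 = design["snp"]
    s2 = s1.copy()
    s2.iloc[:20] = 2.0 - s2.iloc[:20]  # r^2 still well above 0.5
    with pytest.warns(errors.CollinearityWarning):
        table = interaction_model(s1, s2, traits, phi, ped)
    assert len(table) == 3  # fit is still returned


def test_dosage_recoding_flips_sign():
    cfg = SimulationConfig(seed=43, n_pedigrees=150, structure=("nuclear", 2),
                           n_markers=1, causal_markers=[(0, 0.3, 0.3)])
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
    f1 = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=snp.to_frame()),
                           phi, ped)
    f2 = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=(2 - snp).to_frame()),
                           phi, ped)
    assert f1.coef("trait1:snp") == pytest.approx(-f2.coef("trait1:snp"), abs=1e-8)


@pytest.mark.parametrize("b1,b2,maf,sg12,expected", [
    (0.0, 0.5, 0.2, 0.3, 0.0),
    (0.2, 0.2, 0.5, 0.2, 0.10),
])
def test_variance_explained_formula(b1, b2, maf, sg12, expected):
    assert variance_explained(b1, b2, maf, sg12) == pytest.approx(expected)


def test_variance_explained_errors():
    with pytest.raises(errors.DegenerateError):
        variance_explained(0.1, 0.1, 0.2, 0.0)
    with pytest.raises(errors.RangeError):
        variance_explained(0.1, 0.1, 1.5, 0.2)


def test_variance_explained_single_snp_architecture():
    # the causal SNP is the only source of genetic covariance: proportion ~ 1
    cfg = SimulationConfig(seed=44, n_pedigrees=1500, structure=("nuclear", 3),
                           n_markers=1, maf_spectrum=[0.5],
                           causal_markers=[(0, 0.5, 0.5)],
                           sigma_g=((1e-6, 0.0), (0.0, 1e-6)),
                           sigma_e=((1.0, 0.0), (0.0, 1.0)),
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    # no-SNP model: the SNP's covariance contribution loads onto sigma_g12
    base = fit_bivariate_the(TheModelSpec(traits=traits), phi, ped)
    snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=snp.to_frame()),
                            phi, ped)
    maf = float(g.maf()[0])
    prop = variance_explained(fit.coef("trait1:snp"), fit.coef("trait2:snp"),
                              maf, base.vc.sigma_g[0, 1])
    assert prop == pytest.approx(1.0, abs=0.25)  # denominator noise at this n


def test_genome_scan_finds_planted_marker_and_modes_agree():
    cfg = SimulationConfig(seed=45, n_pedigrees=150, structure=("nuclear", 2),
                           n_markers=20, causal_markers=[(7, 0.5, 0.5)],
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped, g, pheno, _ = simulate_dataset(cfg)
    phi = kinship(ped)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    fast = genome_scan(g, traits, phi, ped, mode="fast")["results"]
    assert fast.loc[fast["p"].idxmin(), "marker_id"] == "m8"
    exact = genome_scan(g, traits, phi, ped, mode="exact")["results"]
    null_mask = fast["marker_id"] != "m8"
    dlog = np.abs(np.log10(fast.loc[null_mask, "p"].to_numpy())
                  - np.log10(exact.loc[null_mask, "p"].to_numpy()))
    assert np.nanmax(dlog) < 0.2


def test_genomic_lambda_uniform_and_scaling():
    n = 5000
    p_unif = (np.arange(1, n + 1) - 0.5) / n
    assert genomic_lambda(p_unif, df=2) == pytest.approx(1.0, abs=0.01)
    chi = stats.chi2.isf(p_unif, 2)
    p_doubled = stats.chi2.sf(2 * chi, 2)
    assert genomic_lambda(p_doubled, df=2) == pytest.approx(2.0, abs=0.02)
    with pytest.raises(errors.RangeError):
        genomic_lambda(p_unif[:50], df=2)


def test_bivariate_power_dominates_univariate_concordant_effects():
    # fixed grid point: same-direction SNP effect on both traits
    cfg = SimulationConfig(seed=46, n_pedigrees=150, structure=("nuclear", 2),
                           n_markers=1, maf_spectrum=[0.3],
                           causal_markers=[(0, 0.18, 0.18)],
                           age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped = simulate_pedigrees(cfg)
    phi = kinship(ped)
    rng = np.random.default_rng(46)
    reps = 60
    p_biv, p_uni1, p_uni2 = [], [], []
    for _ in range(reps):
        g, _ = gene_drop(ped, cfg, rng)
        pheno = simulate_traits(ped, g, cfg, rng, phi=phi)
        traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
        snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
        fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=snp.to_frame()),
                                phi, ped)
        p_biv.append(wald_test(fit, ["trait1:snp", "trait2:snp"])[2])
        p_uni1.append(wald_test(fit, ["trait1:snp"])[2])
        p_uni2.append(wald_test(fit, ["trait2:snp"])[2])
    alpha = 0.05
    power_biv = np.mean(np.array(p_biv) < alpha)
    power_uni = max(np.mean(np.array(p_uni1) < alpha),
                    np.mean(np.array(p_uni2) < alpha))
    assert power_biv >= power_uni


def test_nonconvergence_reported_not_silent():
    ped, phi, traits, design = _unrelated_cohort(100, seed=6)
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design,
                                         max_iter=1, tol=1e-15), phi, ped)
    assert fit.converged is False


def test_robust_sandwich_se_close_to_model_based():
    ped, phi, traits, design = _unrelated_cohort(400, seed=9)
    model = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design),
                              phi, ped)
    robust = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=design,
                                            robust_se=True), phi, ped)
    # identical point estimates; SEs agree to first order on well-specified data
    assert robust.coef("t1:snp") == pytest.approx(model.coef("t1:snp"), abs=1e-10)
    assert robust.se("t1:snp") == pytest.approx(model.se("t1:snp"), rel=0.25)


def test_null_scan_bonferroni_calibration():
    # 200 null markers: the Bonferroni threshold 0.05/200 should protect the
    # scan-wise error in >= 90% of replicates
    cfg = SimulationConfig(seed=47, n_pedigrees=100, structure=("nuclear", 3),
                           n_markers=200, age_slope=(0.0, 0.0),
                           sex_shift=(0.0, 0.0))
    ped = simulate_pedigrees(cfg)
    phi = kinship(ped)
    rng = np.random.default_rng(47)
    clean = 0
    reps = 100
    thr = 0.05 / 200
    for _ in range(reps):
        g, _ = gene_drop(ped, cfg, rng)
        pheno = simulate_traits(ped, g, cfg, rng, phi=phi)
        traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
        res = genome_scan(g, traits, phi, ped, mode="fast")["results"]
        clean += (res["p"].min() >= thr)
    assert clean / reps >= 0.90
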