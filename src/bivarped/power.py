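"""Seeded simulation studies of the two-level HE Wald test.

These drive both the test suite and the acceptance script: empirical power
of the joint bivariate test for a large-effect rare SNP in extended
pedigrees, and type-I error / inflation checks under the null. Pedigree
structure and kinship are built once and reused across replicates; each
replicate redraws genotypes and traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hemodel import TheModelSpec, fit_bivariate_the, genomic_lambda, wald_test
from .pedigree import kinship
from .simulate import SimulationConfig, gene_drop, simulate_pedigrees, simulate_traits

__all__ = ["bivariate_power", "null_pvalues", "null_lambda"]


def _replicate_pvalue(ped, phi, cfg, rng, traits_cols=("trait1", "trait2"),
                      snp_index=0):
    g, _ = gene_drop(ped, cfg, rng)
    pheno = simulate_traits(ped, g, cfg, rng, phi=phi)
    traits = pheno.set_index("subject_id")[list(traits_cols)]
    snp = pd.Series(g.values[:, snp_index], index=g.subject_ids, name="snp")
    fit = fit_bivariate_the(TheModelSpec(traits=traits, fixed_effects=snp.to_frame()),
                            phi, ped)
    which = [f"{t}:snp" for t in traits_cols]
    _, _, p = wald_test(fit, which)
    return p, fit


def bivariate_power(n_pedigrees: int = 300, structure="three_generation",
                    maf: float = 0.01, beta: tuple[float, float] = (1.3, 1.3),
                    h2: float = 0.3, genetic_corr: float = 0.5,
                    alpha: float = 2.66e-7, n_replicates: int = 200,
                    seed: int = 1) -> dict:
    """Empirical power of the joint 2-df Wald test for one causal SNP.

    Traits carry residual polygenic heritability ``h2`` with genetic
    correlation ``genetic_corr`` on top of the SNP effect; power is the
    fraction of replicates rejecting at ``alpha``.
    """
    sg = h2 * np.array([[1.0, genetic_corr], [genetic_corr, 1.0]])
    se = (1.0 - h2) * np.eye(2)
    cfg = SimulationConfig(
        seed=seed, n_pedigrees=n_pedigrees, structure=structure, n_markers=1,
        maf_spectrum=[maf], causal_markers=[(0, beta[0], beta[1])],
        sigma_g=tuple(map(tuple, sg)), sigma_e=tuple(map(tuple, se)),
        age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped = simulate_pedigrees(cfg)
    phi = kinship(ped)
    rng = np.random.default_rng(seed)
    rejections = 0
    pvals = []
    for _ in range(n_replicates):
        p, _ = _replicate_pvalue(ped, phi, cfg, rng)
        pvals.append(p)
        rejections += p < alpha
    return {"power": rejections / n_replicates, "alpha": alpha,
            "n_replicates": n_replicates, "n_subjects": len(ped.ids),
            "pvalues": np.array(pvals)}


def null_pvalues(n_replicates: int = 2000, n_pedigrees: int = 150,
                 structure=("nuclear", 2), seed: int = 2,
                 univariate: bool = False) -> np.ndarray:
    """P-values of the SNP Wald test over replicates with no SNP effect."""
    cfg = SimulationConfig(
        seed=seed, n_pedigrees=n_pedigrees, structure=structure, n_markers=1,
        maf_spectrum=[0.3], age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped = simulate_pedigrees(cfg)
    phi = kinship(ped)
    rng = np.random.default_rng(seed)
    cols = ("trait1",) if univariate else ("trait1", "trait2")
    return np.array([
        _replicate_pvalue(ped, phi, cfg, rng, traits_cols=cols)[0]
        for _ in range(n_replicates)
    ])


def null_lambda(n_markers: int = 10_000, n_pedigrees: int = 125,
                structure=("nuclear", 2), seed: int = 3) -> float:
    """Genomic inflation factor of a fast-mode scan over null markers."""
    from .hemodel import genome_scan

    cfg = SimulationConfig(
        seed=seed, n_pedigrees=n_pedigrees, structure=structure,
        n_markers=n_markers, age_slope=(0.0, 0.0), sex_shift=(0.0, 0.0))
    ped = simulate_pedigrees(cfg)
    phi = kinship(ped)
    rng = np.random.default_rng(seed)
    g, _ = gene_drop(ped, cfg, rng)
    pheno = simulate_traits(ped, g, cfg, rng, phi=phi)
    traits = pheno.set_index("subject_id")[["trait1", "trait2"]]
    scan = genome_scan(g, traits, phi, ped, mode="fast")
    return genomic_lambda(scan["results"]["p"].dropna().to_numpy(), df=2)
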