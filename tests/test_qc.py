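import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from bivarped import errors
from bivarped.io import GenotypeMatrix, MarkerMeta
from bivarped.qc import (hwe_chi2, hwe_exact, hwe_filter, ld_prune, ld_r2,
                         site_and_sample_filters)


def _matrix(values, imputed=None, rsq=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    metas = []
    for j in range(m):
        imp = bool(imputed and j in imputed)
        metas.append(MarkerMeta(f"m{j}", "1", (j + 1) * 100, "A", "G",
                                is_imputed=imp, rsq=(rsq or {}).get(j) if imp else None))
    return GenotypeMatrix([f"s{i}" for i in range(n)], metas, values)


def test_marker_call_rate_filter():
    vals = np.ones((100, 2))
    vals[:3, 0] = np.nan  # 97% call rate -> removed
    vals[:, 1] = np.tile([0, 1], 50)
    g, report = site_and_sample_filters(_matrix(vals), maf_min=0.0)
    assert g.marker_ids() == ["m1"]
    assert report.steps[0]["removed"] == 1


def test_maf_filter_boundary():
    n = 1000
    vals = np.zeros((n, 2))
    vals[:19, 0] = 1.0   # MAF 0.0095 < 0.02 -> removed
    vals[:42, 1] = 1.0   # MAF 0.021 -> kept
    g, report = site_and_sample_filters(_matrix(vals))
    assert g.marker_ids() == ["m1"]


def test_rsq_and_subject_filters():
    vals = np.tile([0.0, 1.0, 2.0, 1.0], (4, 6)).reshape(16, 6)[:10, :6]
    vals = np.tile(np.array([0, 1, 2, 1, 0, 1], dtype=float), (10, 1))
    vals[0, :3] = np.nan  # subject 0 call rate 50% among remaining markers
    g = _matrix(vals, imputed={5}, rsq={5: 0.5})
    out, report = site_and_sample_filters(g, maf_min=0.0, marker_call_min=0.8)
    assert "m5" not in out.marker_ids()          # RSQ 0.5 < 0.8
    assert "s0" not in out.subject_ids           # low call rate
    by = {s["filter"]: s for s in report.steps}
    assert by["imputation_rsq"]["removed"] == 1
    assert by["subject_call_rate"]["removed"] == 1


def test_qc_planted_violations_counts(rng):
    # planted: 2 low-call markers, 3 low-MAF markers among 20
    n = 500
    vals = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
    for j in (0, 1):
        vals[: int(0.05 * n), j] = np.nan
    for j in (2, 3, 4):
        vals[:, j] = 0.0
        vals[:5, j] = 1.0
    g, report = site_and_sample_filters(_matrix(vals))
    # enumeration oracle: recount violations directly
    call = 1 - np.isnan(vals).mean(axis=0)
    maf = np.minimum(np.nanmean(vals, axis=0) / 2, 1 - np.nanmean(vals, axis=0) / 2)
    n_call = int((call < 0.98).sum())
    n_maf = int(((call >= 0.98) & (maf < 0.02)).sum())
    assert report.steps[0]["removed"] == n_call == 2
    assert report.steps[1]["removed"] == n_maf == 3
    assert g.n_markers == 20 - n_call - n_maf


def test_qc_deterministic(rng):
    vals = rng.binomial(2, 0.25, size=(200, 30)).astype(float)
    vals[rng.random(vals.shape) < 0.01] = np.nan
    g = _matrix(vals)
    out1, r1 = site_and_sample_filters(g)
    out2, r2 = site_and_sample_filters(g)
    assert out1.marker_ids() == out2.marker_ids()
    assert r1.steps == r2.steps


def test_empty_after_qc():
    vals = np.zeros((50, 1))
    with pytest.raises(errors.EmptyAfterQcError):
        site_and_sample_filters(_matrix(vals))  # monomorphic -> MAF filter kills


def _hwe_oracle(n_rr, n_h, n_aa):
    """Exact-fraction enumeration of the conditional HWE test."""
    n = n_rr + n_h + n_aa
    n_alt = n_h + 2 * min(n_rr, n_aa)
    if n_alt == 0:
        return 1.0
    probs = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        na = (n_alt - h) // 2
        nr = n - na - h
        probs[h] = Fraction(2**h * math.factorial(n),
                            math.factorial(na) * math.factorial(h) * math.factorial(nr))
    tot = sum(probs.values())
    p_obs = probs[n_h]
    return float(sum(v for v in probs.values() if v <= p_obs) / tot)


def test_hwe_exact_two_individuals():
    assert hwe_exact(1, 0, 1) == pytest.approx(1.0 / 3.0)


def test_hwe_exact_matches_enumeration_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(1, 51))
        n_rr = int(rng.integers(0, n + 1))
        n_h = int(rng.integers(0, n - n_rr + 1))
        n_aa = n - n_rr - n_h
        assert hwe_exact(n_rr, n_h, n_aa) == pytest.approx(
            _hwe_oracle(n_rr, n_h, n_aa), abs=1e-10)


def test_hwe_exact_parity_support():
    # 3 alt alleles among n=5 -> het count must be odd; all-hom impossible
    p = hwe_exact(3, 1, 1)
    assert 0 < p <= 1.0


def test_hwe_pvalues_uniform_under_null(rng):
    # the exact test's p-values are discrete and conservative, so plain KS
    # rejects by construction; the randomized (fuzzy) version, which smooths
    # the atom at the observed outcome, is exactly uniform under the null
    from bivarped.qc import _hwe_het_probs

    n_markers, n_founders = 2000, 500
    pvals = []
    for _ in range(n_markers):
        maf = rng.uniform(0.05, 0.5)
        g = rng.binomial(1, maf, size=(n_founders, 2)).sum(axis=1)
        n_rr, n_h, n_aa = int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())
        p_exact = hwe_exact(n_rr, n_h, n_aa)
        n_alt = n_h + 2 * min(n_rr, n_aa)
        hs, probs = _hwe_het_probs(n_h, n_founders, n_alt)
        p_atom = float(probs[hs == n_h][0])
        pvals.append(p_exact - rng.uniform(0, p_atom))
        assert p_exact <= 1.0 and p_exact >= p_atom  # validity of the atom sum
    d, p = stats.kstest(pvals, "uniform")
    assert p > 1e-3


def test_hwe_chi2_close_to_exact_at_large_n():
    assert hwe_chi2(400, 320, 80) == pytest.approx(hwe_exact(400, 320, 80), rel=0.5)


def test_ld_r2_basics(rng):
    x = rng.binomial(2, 0.3, 500).astype(float)
    assert ld_r2(x, x) == pytest.approx(1.0)
    assert ld_r2(x, 2.0 - x) == pytest.approx(1.0)
    with pytest.raises(errors.DegenerateError):
        ld_r2(x, np.ones(500))


def test_ld_r2_independent_markers(rng):
    x = rng.binomial(2, 0.3, 5000).astype(float)
    y = rng.binomial(2, 0.4, 5000).astype(float)
    assert ld_r2(x, y) < 0.01


def test_ld_prune_duplicate_marker(rng):
    x = rng.binomial(2, 0.3, 300).astype(float)
    y = rng.binomial(2, 0.45, 300).astype(float)
    g = _matrix(np.column_stack([x, x, y]))
    out, removed = ld_prune(g)
    assert len(removed) == 1
    assert out.n_markers == 2


def test_ld_prune_identity_when_independent(rng):
    vals = rng.binomial(2, 0.3, size=(400, 10)).astype(float)
    out, removed = ld_prune(_matrix(vals))
    assert removed == [] and out.n_markers == 10


def test_ld_prune_exhaustive_verification(rng):
    # 50-marker block with planted LD: each marker correlates with the previous
    n = 400
    vals = np.zeros((n, 50))
    vals[:, 0] = rng.binomial(2, 0.4, n)
    for j in range(1, 50):
        copy = rng.random(n) < 0.97
        vals[:, j] = np.where(copy, vals[:, j - 1], rng.binomial(2, 0.4, n))
    out, removed = ld_prune(_matrix(vals), window=20, step=5, r2_max=0.8)
    assert len(removed) > 0
    for a in range(out.n_markers):
        for b in range(a + 1, out.n_markers):
            if b - a < 20:  # within any window
                assert ld_r2(out.values[:, a], out.values[:, b]) <= 0.8 + 1e-12


def test_ld_prune_requires_sorted_positions():
    metas = [MarkerMeta("a", "1", 200, "A", "G"), MarkerMeta("b", "1", 100, "A", "G")]
    g = GenotypeMatrix(["s1", "s2", "s3"],
                       metas, np.array([[0, 1], [1, 0], [2, 1]], dtype=float))
    with pytest.raises(errors.RangeError):
        ld_prune(g)


def test_hwe_filter_removes_planted_violation(rng):
    n = 400
    good = rng.binomial(1, 0.3, size=(n, 2)).sum(axis=1).astype(float)
    bad = np.where(rng.random(n) < 0.5, 0.0, 2.0)  # no hets at ~50% frequency
    g = _matrix(np.column_stack([good, bad]))
    out, n_removed, pvals = hwe_filter(g, p_min=1e-6)
    assert n_removed == 1
    assert out.marker_ids() == ["m0"]
    assert pvals[1] < 1e-6


def test_autosomes_only():
    from bivarped.qc import autosomes_only

    metas = [MarkerMeta("a1", "1", 100, "A", "G"),
             MarkerMeta("x1", "X", 200, "A", "G"),
             MarkerMeta("a2", "22", 300, "A", "G")]
    g = GenotypeMatrix(["s1", "s2"], metas,
                       np.array([[0, 1, 2], [1, 1, 0]], dtype=float))
    out, n_dropped = autosomes_only(g)
    assert out.marker_ids() == ["a1", "a2"] and n_dropped == 1
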