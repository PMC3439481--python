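"""Marker and sample quality control with LD pruning.

The cleaning pipeline mirrors standard family-GWAS practice: drop markers
with low call rate, low minor allele frequency, Hardy-Weinberg
disequilibrium (exact test on founders) and, for imputed markers, poor
imputation quality; then drop subjects with low call rates among the
remaining markers; finally prune one member of each marker pair in high LD
within sliding windows. MAF and HWE are computed on founders only, to avoid
pseudo-replication from relatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateError, EmptyAfterQcError, InsufficientDataError, RangeError
from .io import GenotypeMatrix

__all__ = [
    "QcReport",
    "autosomes_only",
    "site_and_sample_filters",
    "hwe_exact",
    "hwe_chi2",
    "hwe_filter",
    "ld_r2",
    "ld_prune",
]

AUTOSOMES = {str(c) for c in range(1, 23)}


def autosomes_only(g: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Drop X/Y/MT and other non-autosomal markers (analysis is autosomal)."""
    keep = [m.marker_id for m in g.markers if m.chromosome in AUTOSOMES]
    return g.subset(marker_ids=keep), g.n_markers - len(keep)


@dataclass
class QcReport:
    """Per-filter removal counts, in application order."""

    steps: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, name: str, removed: int, kind: str, threshold) -> None:
        self.steps.append({"filter": name, "removed": removed,
                           "kind": kind, "threshold": threshold})

    def total_removed(self, kind: str) -> int:
        return sum(s["removed"] for s in self.steps if s["kind"] == kind)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.steps)


def site_and_sample_filters(g: GenotypeMatrix,
                            founder_ids: Sequence[str] | None = None,
                            marker_call_min: float = 0.98,
                            maf_min: float = 0.02,
                            subject_call_min: float = 0.98,
                            rsq_min: float = 0.8) -> tuple[GenotypeMatrix, QcReport]:
    """Apply marker call-rate, MAF, imputation-quality and subject call-rate filters.

    Order: marker call rate -> MAF (founders when given) -> RSQ (imputed
    markers only) -> subject call rate computed among the remaining markers.
    """
    for name, t in (("marker_call_min", marker_call_min), ("maf_min", maf_min),
                    ("subject_call_min", subject_call_min), ("rsq_min", rsq_min)):
        if not 0.0 <= t <= 1.0:
            raise RangeError(f"{name}={t} outside [0, 1]")
    report = QcReport()
    marker_ids = np.array(g.marker_ids())

    cr = g.call_rate_per_marker()
    keep = cr >= marker_call_min
    report.add("marker_call_rate", int((~keep).sum()), "marker", marker_call_min)
    g = g.subset(marker_ids=list(marker_ids[keep]))
    marker_ids = marker_ids[keep]

    maf = g.maf(founder_ids)
    keep = ~np.isnan(maf) & (maf >= maf_min)
    report.add("maf", int((~keep).sum()), "marker", maf_min)
    g = g.subset(marker_ids=list(marker_ids[keep]))
    marker_ids = marker_ids[keep]

    rsq = np.array([m.rsq if m.is_imputed else np.nan for m in g.markers])
    keep = np.isnan(rsq) | (rsq >= rsq_min)
    report.add("imputation_rsq", int((~keep).sum()), "marker", rsq_min)
    g = g.subset(marker_ids=list(marker_ids[keep]))

    if g.n_markers == 0:
        raise EmptyAfterQcError("no markers left after marker filters")

    scr = g.call_rate_per_subject()
    keep_s = scr >= subject_call_min
    report.add("subject_call_rate", int((~keep_s).sum()), "subject", subject_call_min)
    g = g.subset(subject_ids=[s for s, k in zip(g.subject_ids, keep_s) if k])
    if g.n_subjects == 0:
        raise EmptyAfterQcError("no subjects left after subject call-rate filter")
    report.notes.append("X-chromosome sex check: not performed (autosomes only)")
    return g, report


def _hwe_het_probs(n_het_obs: int, n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional log-probabilities of each possible heterozygote count.

    Given n diploid individuals and n_alt copies of the minor allele, the
    heterozygote count h has support {parity(n_alt), parity+2, ...} and
    P(h | n, n_alt) proportional to n! 2^h / ((n_alt-h)/2)! h! ((2n-n_alt-h)/2)!.
    """
    hs = np.arange(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2)
    n_aa = (n_alt - hs) // 2
    n_rr = n - n_aa - hs
    logp = (hs * np.log(2.0) - gammaln(n_aa + 1) - gammaln(hs + 1) - gammaln(n_rr + 1))
    logp -= logp.max()
    p = np.exp(logp)
    return hs, p / p.sum()


def hwe_exact(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the conditional probabilities (given sample size and allele count)
    of all heterozygote counts no more probable than the observed one.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise RangeError("genotype counts must be >= 0")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise RangeError("need at least one genotyped individual")
    n_alt = n_het + 2 * min(n_homref, n_homalt)  # fold so alt is the minor allele
    if n_alt == 0:
        return 1.0
    hs, probs = _hwe_het_probs(n_het, n, n_alt)
    p_obs = probs[hs == n_het][0]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def hwe_chi2(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Asymptotic 1-df chi-square Hardy-Weinberg test (optional alternative)."""
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise RangeError("need at least one genotyped individual")
    p = (2 * n_homref + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_homref, n_het, n_homalt], dtype=float)
    x2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(x2, df=1))


def hwe_filter(g: GenotypeMatrix, founder_ids: Sequence[str] | None = None,
               p_min: float = 1e-6, method: str = "exact"
               ) -> tuple[GenotypeMatrix, int, np.ndarray]:
    """Drop markers out of Hardy-Weinberg equilibrium (P < p_min) among founders.

    Dosage markers (non-integer calls) are left untouched. Returns the
    filtered matrix, the number removed, and per-marker p-values (NaN where
    the test was not applicable).
    """
    test = hwe_exact if method == "exact" else hwe_chi2
    rows = ([g.subject_index(s) for s in founder_ids if s in g._index]
            if founder_ids is not None else list(range(g.n_subjects)))
    v = g.values[rows]
    pvals = np.full(g.n_markers, np.nan)
    for j in range(g.n_markers):
        col = v[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or not np.all(np.isin(col, (0.0, 1.0, 2.0))):
            continue
        pvals[j] = test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    keep = np.isnan(pvals) | (pvals >= p_min)
    marker_ids = np.array(g.marker_ids())
    out = g.subset(marker_ids=list(marker_ids[keep]))
    return out, int((~keep).sum()), pvals


def ld_r2(x, y) -> float:
    """Composite LD: squared Pearson correlation of genotype/dosage values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    if keep.sum() < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {int(keep.sum())}")
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateError("monomorphic marker in ld_r2")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_prune(values: np.ndarray, maf: np.ndarray, pos: np.ndarray,
                  active: np.ndarray, idx: np.ndarray, r2_max: float) -> None:
    """Greedy removal inside one window until no pair exceeds r2_max."""
    while True:
        live = idx[active[idx]]
        if live.size < 2:
            return
        v = values[:, live]
        with np.errstate(invalid="ignore"):
            mask = ~np.isnan(v)
            # pairwise complete-case correlation via masked standardization
            r2 = np.zeros((live.size, live.size))
            for a in range(live.size):
                for b in range(a + 1, live.size):
                    keep = mask[:, a] & mask[:, b]
                    if keep.sum() < 3:
                        continue
                    xa, xb = v[keep, a], v[keep, b]
                    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                        continue
                    c = np.corrcoef(xa, xb)[0, 1]
                    r2[a, b] = r2[b, a] = c * c
        worst = np.unravel_index(np.argmax(r2), r2.shape)
        if r2[worst] <= r2_max:
            return
        a, b = live[worst[0]], live[worst[1]]
        # drop the lower-MAF member; tie -> larger bp position
        if (maf[a], -pos[a]) < (maf[b], -pos[b]):
            active[a] = False
        else:
            active[b] = False


def ld_prune(g: GenotypeMatrix, window: int = 1500, step: int = 150,
             r2_max: float = 0.8) -> tuple[GenotypeMatrix, list[str]]:
    """Sliding-window LD pruning: remove one of each marker pair with r2 > r2_max.

    Markers must be sorted by (chromosome, position); windows of ``window``
    markers slide by ``step`` within each chromosome. The removed member of a
    pair is the one with lower MAF (tie: larger position). The surviving set
    contains no within-window pair above ``r2_max``.
    """
    chroms = np.array([m.chromosome for m in g.markers])
    pos = np.array([m.position for m in g.markers])
    for c in np.unique(chroms):
        p = pos[chroms == c]
        if np.any(np.diff(p) < 0):
            raise RangeError(f"markers on chromosome {c} not sorted by position")
    maf = g.maf()
    active = np.ones(g.n_markers, dtype=bool)
    for c in np.unique(chroms):
        cidx = np.nonzero(chroms == c)[0]
        start = 0
        while True:
            idx = cidx[start:start + window]
            if idx.size >= 2:
                _window_prune(g.values, maf, pos, active, idx, r2_max)
            if start + window >= cidx.size:
                break
            start += step
    marker_ids = np.array(g.marker_ids())
    removed = list(marker_ids[~active])
    return g.subset(marker_ids=list(marker_ids[active])), removed
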