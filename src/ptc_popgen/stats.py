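"""Per-locus population-genetic statistics.

Implements the estimators used to characterize PTC variation across
populations:

* Hardy-Weinberg equilibrium via the exact test conditional on allele
  counts (robust at the rare-homozygote counts typical of nonsense
  alleles, where the chi-square approximation fails);
* observed / unbiased expected heterozygosity;
* Weir & Cockerham's theta (F_ST) from the a/b/c variance components for
  diploid biallelic data;
* the G_ST family: Nei's G_ST, Hedrick's standardized G'_ST and Jost's D,
  from sample-size-corrected gene diversities H_S and H_T;
* percentile bootstrap confidence intervals, resampling individuals with
  replacement within populations;
* the paired Wilcoxon signed-rank comparison of two cohorts' DAF vectors.

Array-oriented entry points accept per-population arrays shaped (r,) for a
single locus or (r, L) for L loci, so genome-scale simulations stay
vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import wilcoxon

from .panel import PanelMap
from .polarize import PopAlleleCounts

__all__ = [
    "HweResult", "DifferentiationResult", "genotype_spectrum", "hwe_test",
    "heterozygosity", "weir_cockerham_theta", "multilocus_theta", "gst_family",
    "pop_allele_stats",
    "differentiation", "bootstrap_ci", "compare_cohort_daf",
]


@dataclass(frozen=True)
class HweResult:
    n_AA: int
    n_Aa: int
    n_aa: int
    p: float                      # ancestral allele frequency
    q: float                      # derived allele frequency
    expected: tuple[float, float, float]  # (p^2, 2pq, q^2)
    p_value: float


@dataclass
class DifferentiationResult:
    """Per-locus differentiation summary across r populations."""

    locus: str
    r: int
    n: tuple[int, ...]            # diploids genotyped per population
    H_S: float
    H_T: float
    a: float
    b: float
    c: float
    theta: float                  # Weir-Cockerham F_ST (may be negative / NaN)
    G_ST: float
    G_prime_ST: float
    D: float                      # Jost's D
    theta_ci: tuple[float, float] | None = None
    gst_ci: tuple[float, float] | None = None
    bootstrap_B: int | None = None
    ci_level: float | None = None


# -- genotype spectra and HWE ---------------------------------------------

def genotype_spectrum(dosages: np.ndarray, samples: list[str], panel: PanelMap
                      ) -> tuple[dict[str, tuple[int, int, int]], tuple[int, int, int]]:
    """Per-population and pooled (n_AA, n_Aa, n_aa) from a dosage vector;
    missing (-1) genotypes are excluded. Pooled = sum over populations."""
    idx = panel.sample_indices_by_population(samples)
    per_pop: dict[str, tuple[int, int, int]] = {}
    for pop, rows in idx.items():
        d = dosages[rows]
        per_pop[pop] = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    pooled = tuple(int(sum(c[i] for c in per_pop.values())) for i in range(3))
    return per_pop, pooled


def _log_hwe_prob(n_ab: np.ndarray, n: int, n_b: int) -> np.ndarray:
    """log P(heterozygote count = n_ab | n diploids, n_b minor alleles)
    under HWE (conditional on allele counts; Levene/Haldane distribution)."""
    n_bb = (n_b - n_ab) // 2
    n_aa = n - n_ab - n_bb
    return (
        np.log(2.0) * n_ab
        + gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_ab + 1) - gammaln(n_bb + 1)
        + gammaln(n_b + 1) + gammaln(2 * n - n_b + 1) - gammaln(2 * n + 1)
    )


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Exact Hardy-Weinberg test for biallelic genotype counts.

    The p-value sums, over all heterozygote counts compatible with the
    observed allele counts, the conditional probabilities of tables as or
    less probable than the observed one (two-sided, probability ordering).
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa
    q = n_a / (2 * n)
    p = 1.0 - q
    expected = (p * p, 2 * p * q, q * q)
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return HweResult(n_AA, n_Aa, n_aa, p, q, expected, 1.0)
    # heterozygote count shares the parity of the minor allele count
    het_obs = n_Aa
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = _log_hwe_prob(hets, n, n_minor)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het_obs]
    if p_obs.size == 0:  # inconsistent counts cannot occur from real data
        raise ValueError("heterozygote count incompatible with allele counts")
    pval = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return HweResult(n_AA, n_Aa, n_aa, p, q, expected, min(pval, 1.0))


# -- heterozygosity --------------------------------------------------------

def heterozygosity(per_pop_counts: dict[str, PopAlleleCounts]
                   ) -> tuple[dict[str, tuple[float, float]], float]:
    """Observed and unbiased expected heterozygosity per population.

    H_obs is the heterozygote fraction; H_exp is Nei's unbiased gene
    diversity (2n/(2n-1)) * 2*p*q with n the genotyped diploids. Returns
    ({pop: (H_obs, H_exp)}, pooled_H_exp) where the pooled value uses the
    pooled allele frequencies with the same small-sample correction.
    Populations without genotyped individuals are excluded with a warning.
    """
    per_pop: dict[str, tuple[float, float]] = {}
    tot_a = tot_alleles = 0
    tot_n = 0
    for pop, c in per_pop_counts.items():
        n = c.n_genotyped
        if n == 0:
            warnings.warn(f"population {pop!r} has no genotyped individuals; excluded")
            continue
        q = c.n_a / (2 * n)
        h_obs = c.n_Aa / n
        h_exp = (2 * n / (2 * n - 1)) * 2 * q * (1 - q) if n > 0 else 0.0
        per_pop[pop] = (h_obs, h_exp)
        tot_a += c.n_a
        tot_alleles += 2 * n
        tot_n += n
    if tot_alleles == 0:
        raise ValueError("no genotyped individuals in any population")
    q = tot_a / tot_alleles
    pooled = (tot_alleles / (tot_alleles - 1)) * 2 * q * (1 - q) if tot_alleles > 1 else 0.0
    return per_pop, pooled


# -- Weir-Cockerham theta --------------------------------------------------

def weir_cockerham_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham variance components for diploid biallelic loci.

    Parameters
    ----------
    n, p, h:
        Per-population sample sizes (diploids genotyped), derived-allele
        frequencies and observed heterozygote fractions, shaped (r,) for a
        single locus or (r, L) for L loci.

    Returns
    -------
    (a, b, c, theta):
        The among-population (a), among-individual-within-population (b)
        and within-individual (c) components, and theta = a/(a+b+c).
        Globally monomorphic loci yield NaN theta. Negative estimates are
        reported as-is (the estimator is unbiased around zero for
        undifferentiated populations).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    single = n.ndim == 1
    if single:
        n, p, h = n[:, None], p[:, None], h[:, None]
    r = n.shape[0]
    if r < 2:
        raise ValueError("at least two populations required")

    nbar = n.mean(axis=0)
    nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    if single:
        return a[0], b[0], c[0], theta[0]
    return a, b, c, theta


def multilocus_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta: the ratio of summed variance
    components, sum(a) / sum(a+b+c) over loci. This is the estimator the
    original moment method defines for sets of loci; it is consistent for
    the Balding-Nichols F where the mean of per-locus ratios is biased
    toward zero (Jensen's inequality on the ratio)."""
    a, b, c, _ = weir_cockerham_theta(n, p, h)
    denom = np.nansum(a + b + c)
    if denom == 0:
        return float("nan")
    return float(np.nansum(a) / denom)


# -- G_ST family -----------------------------------------------------------

def gst_family(n: np.ndarray, p: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """H_S, H_T, G_ST, Hedrick's G'_ST and Jost's D for biallelic loci.

    H_S is the unweighted mean over the k populations of the within-
    population gene diversity 2*p_i*(1-p_i); H_T is the total gene
    diversity 2*pbar*(1-pbar) from the unweighted mean allele frequency
    (plain Nei diversities: identical populations then give exactly 0 and
    fully fixed population pairs exactly 1; the small-sample-corrected
    per-population estimator lives in :func:`heterozygosity`). Then

        G_ST  = (H_T - H_S) / H_T
        G'_ST = G_ST * (k - 1 + H_S) / ((k - 1) * (1 - H_S))
        D     = (k / (k - 1)) * (H_T - H_S) / (1 - H_S)

    Undefined cases (H_T = 0 for G_ST; H_S = 1 for G'_ST and D) are NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    single = n.ndim == 1
    if single:
        n, p = n[:, None], p[:, None]
    k = n.shape[0]
    if k < 2:
        raise ValueError("at least two populations required")
    H_S = (2 * p * (1 - p)).mean(axis=0)
    pbar = p.mean(axis=0)
    H_T = 2 * pbar * (1 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        G_ST = np.where(H_T > 0, (H_T - H_S) / np.where(H_T > 0, H_T, 1.0), np.nan)
        denom = (k - 1) * (1 - H_S)
        Gp = np.where(H_S < 1, G_ST * (k - 1 + H_S) / np.where(denom != 0, denom, 1.0), np.nan)
        D = np.where(H_S < 1, (k / (k - 1)) * (H_T - H_S) / np.where(
            H_S < 1, 1 - H_S, 1.0), np.nan)
    if single:
        return H_S[0], H_T[0], G_ST[0], Gp[0], D[0]
    return H_S, H_T, G_ST, Gp, D


# -- array helpers ---------------------------------------------------------

def pop_allele_stats(genotypes: np.ndarray, pop_indices: dict[str, list[int]]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) arrays shaped (r, L) from a (samples x loci) derived-dosage
    matrix with -1 for missing, and sample indices per population."""
    r = len(pop_indices)
    L = genotypes.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for k, rows in enumerate(pop_indices.values()):
        g = genotypes[rows]
        called = g >= 0
        n_k = called.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_k = np.where(called, g, 0).sum(axis=0) / np.maximum(2 * n_k, 1)
            h_k = (g == 1).sum(axis=0) / np.maximum(n_k, 1)
        n[k], p[k], h[k] = n_k, p_k, h_k
    return n, p, h


def counts_to_nph(per_pop_counts: dict[str, PopAlleleCounts]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ns, ps, hs = [], [], []
    for c in per_pop_counts.values():
        m = c.n_genotyped
        ns.append(m)
        ps.append(c.n_a / (2 * m) if m else 0.0)
        hs.append(c.n_Aa / m if m else 0.0)
    return np.array(ns, float), np.array(ps, float), np.array(hs, float)


def differentiation(per_pop_counts: dict[str, PopAlleleCounts], locus: str = "",
                    ) -> DifferentiationResult:
    """Full per-locus differentiation summary from per-population counts."""
    live = {k: c for k, c in per_pop_counts.items() if c.n_genotyped > 0}
    if len(live) < 2:
        raise ValueError("need >= 2 populations with genotyped individuals")
    n, p, h = counts_to_nph(live)
    a, b, c, theta = weir_cockerham_theta(n, p, h)
    H_S, H_T, G_ST, Gp, D = gst_family(n, p)
    return DifferentiationResult(
        locus=locus, r=len(live), n=tuple(int(x) for x in n),
        H_S=float(H_S), H_T=float(H_T), a=float(a), b=float(b), c=float(c),
        theta=float(theta), G_ST=float(G_ST), G_prime_ST=float(Gp), D=float(D),
    )


# -- bootstrap -------------------------------------------------------------

def bootstrap_ci(
    statistic,
    per_pop_genotypes: dict[str, np.ndarray],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI, resampling individuals within populations.

    ``statistic`` maps {population: dosage vector} -> float; it is
    evaluated on B resampled datasets (each population's individuals drawn
    with replacement, sizes preserved). Replicates where the statistic is
    undefined (NaN) are dropped; if more than half are undefined the
    interval is reported as missing (None). Seeded and reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for i in range(B):
        sample = {
            pop: g[rng.integers(0, len(g), size=len(g))]
            for pop, g in per_pop_genotypes.items()
        }
        reps[i] = statistic(sample)
    ok = np.isfinite(reps)
    if ok.sum() <= B / 2:
        warnings.warn("statistic undefined in >50% of bootstrap replicates")
        return None
    alpha = (1 - level) / 2
    lo, hi = np.quantile(reps[ok], [alpha, 1 - alpha])
    return float(lo), float(hi)


def theta_statistic(per_pop_dosages: dict[str, np.ndarray]) -> float:
    """Single-locus Weir-Cockerham theta from per-population dosages, in
    the shape :func:`bootstrap_ci` expects."""
    ns, ps, hs = [], [], []
    for g in per_pop_dosages.values():
        g = g[g >= 0]
        if len(g) == 0:
            continue
        ns.append(len(g))
        ps.append(g.sum() / (2 * len(g)))
        hs.append((g == 1).mean())
    if len(ns) < 2:
        return float("nan")
    _, _, _, theta = weir_cockerham_theta(np.array(ns, float), np.array(ps), np.array(hs))
    return float(theta)


# -- cohort comparison -----------------------------------------------------

def compare_cohort_daf(daf_a, daf_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-variant DAFs
    (exact for small samples, normal approximation with tie correction
    otherwise). All-tied input returns p = 1 with a warning."""
    x = np.asarray(daf_a, dtype=float)
    y = np.asarray(daf_b, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("paired DAF vectors must be equal-length and non-empty")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all DAF pairs tied; p-value = 1")
        return 1.0
    method = "exact" if np.count_nonzero(d) <= 25 else "approx"
    res = wilcoxon(x, y, alternative="two-sided", method=method, zero_method="wilcox")
    return float(res.pvalue)
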