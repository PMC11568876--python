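"""Synthetic genetic data: genotypes with LD, and phenotypes from both model
families, so every pipeline is exercisable without external downloads.

Genotypes are diploid dosages built from two latent-Gaussian haplotypes with
AR(1) correlation along the chromosome, thresholded so each variant's
marginal allele frequency matches its drawn MAF — this gives plausible LD
and Hardy-Weinberg structure at the same time. Phenotypes are exact draws
from the kernel-network hierarchy, or functional signals (linear burden,
region-by-region interaction, smooth nonlinearity) at a requested
signal-to-noise ratio.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io_genetics import (
    GenotypeMatrix,
    Variant,
    write_pheno,
    write_plink_bed,
    write_plink_text,
)
from .kernels import KernelMatrix, product_kernel
from .knn import HiddenKernel

__all__ = [
    "sim_genotypes",
    "sim_knn_phenotype",
    "sim_lmm_phenotype",
    "sim_fnn_phenotype",
    "write_plink",
    "write_pheno",
]

# re-exported writers: the simulator is the usual producer of fixture files
write_plink = write_plink_bed


def sim_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 1000,
) -> GenotypeMatrix:
    """Simulate an n x p dosage matrix with AR(1) linkage disequilibrium.

    Each haplotype is a latent Gaussian AR(1) chain across variants with
    lag-one correlation ``ld_rho``; an allele is carried when the latent
    value falls below the MAF quantile, so the marginal allele frequency of
    variant k equals its MAF regardless of ld_rho. The bim A1 allele ("A")
    is the simulated minor allele; dosages count its copies. Base-pair
    positions are equally spaced with jitter.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=p)
    thresh = stats.norm.ppf(maf)
    dosages = np.zeros((n, p))
    for _hap in range(2):
        z = np.empty((n, p))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, p))
        scale = np.sqrt(1.0 - ld_rho**2)
        for k in range(1, p):
            z[:, k] = ld_rho * z[:, k - 1] + scale * innov[:, k]
        dosages += (z < thresh).astype(float)
    jitter = rng.integers(-spacing_bp // 3, spacing_bp // 3 + 1, size=p)
    bp = spacing_bp * np.arange(1, p + 1) + jitter
    bp = np.maximum.accumulate(bp + np.arange(p) * 0)  # keep increasing
    bp = np.maximum(bp, np.arange(1, p + 1))  # positive
    # enforce strict increase after jitter
    for k in range(1, p):
        if bp[k] <= bp[k - 1]:
            bp[k] = bp[k - 1] + 1
    samples = [("F%d" % i, "I%d" % i) for i in range(1, n + 1)]
    variants = [
        Variant(chrom, f"snp{k + 1}", 0.0, int(bp[k]), "A", "B")
        for k in range(p)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _safe_cholesky(V: np.ndarray) -> np.ndarray:
    n = V.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(V + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * max(np.trace(V) / n, 1.0))
    raise np.linalg.LinAlgError("covariance not PSD even after jitter")


def sim_knn_phenotype(
    x: GenotypeMatrix | list[KernelMatrix],
    hidden: list[HiddenKernel],
    tau: np.ndarray,
    xi: np.ndarray,
    phi: float,
    beta: np.ndarray = (0.0, 0.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact draw from the kernel-network hierarchy.

    Draws m latent unit vectors u ~ N(0, sum_l xi_l K_l), forms each hidden
    kernel H_j from them, draws the genetic effect a ~ N(0, sum_j tau_j H_j)
    and finally y ~ N(Z beta + a, phi I). The fixed design Z is an intercept
    plus one standard-normal covariate. Input kernels default to the product
    kernel on ``x``; a list of precomputed kernels may be passed instead.
    """
    rng = np.random.default_rng(seed)
    if isinstance(x, GenotypeMatrix):
        kernels = [product_kernel(x).values]
    else:
        kernels = [k.values if isinstance(k, KernelMatrix) else k for k in x]
    xi = np.atleast_1d(np.asarray(xi, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if (xi < 0).any() or (tau < 0).any() or phi < 0:
        raise ValueError("variance parameters must be non-negative")
    if len(xi) != len(kernels) or len(tau) != len(hidden):
        raise ValueError("parameter/kernel count mismatch")
    n = kernels[0].shape[0]
    Ku = sum(x_l * K for x_l, K in zip(xi, kernels))
    Cov_a = np.zeros((n, n))
    if tau.sum() > 0 and np.abs(Ku).sum() > 0:
        Lu = _safe_cholesky(Ku)
        for t_j, h in zip(tau, hidden):
            U = Lu @ rng.standard_normal((n, h.m))
            H = (U @ U.T / h.m + h.offset) ** h.degree
            Cov_a += t_j * H
    a = np.zeros(n)
    if Cov_a.any():
        a = _safe_cholesky(Cov_a) @ rng.standard_normal(n)
    Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
    beta = np.asarray(beta, dtype=float)
    y = Z @ beta + a + np.sqrt(phi) * rng.standard_normal(n)
    return y, Z


def sim_lmm_phenotype(
    components: list[np.ndarray] | list[KernelMatrix],
    coeffs,
    beta=(0.0, 0.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian phenotype with an exactly specified marginal covariance.

    Draws y ~ N(Z beta, sum_r coeffs_r V_r). This is the marginal law the
    variance-component estimator targets; unlike the full hierarchy draw of
    :func:`sim_knn_phenotype` (whose conditional genetic covariance is a
    random rank-m matrix) it carries no extra replicate-level variability,
    so it is the right generator for estimator-calibration studies.
    """
    mats = [
        v.values if isinstance(v, KernelMatrix) else np.asarray(v, float)
        for v in components
    ]
    coeffs = np.atleast_1d(np.asarray(coeffs, dtype=float))
    if (coeffs < 0).any() or len(coeffs) != len(mats):
        raise ValueError("need one non-negative coefficient per component")
    rng = np.random.default_rng(seed)
    n = mats[0].shape[0]
    V = sum(c * M for c, M in zip(coeffs, mats))
    y0 = _safe_cholesky(V) @ rng.standard_normal(n)
    Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
    return Z @ np.asarray(beta, dtype=float) + y0, Z


def _burden(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return d[:, idx].mean(axis=1)


def sim_fnn_phenotype(
    x: GenotypeMatrix,
    signal: str = "linear",
    snr: float = 1.0,
    seed: int = 0,
    return_signal: bool = False,
):
    """Continuous phenotype with a functional genetic signal.

    ``linear``: y = <alpha*, G> + e with alpha*(t) = sin(2 pi t) + t over the
    rescaled positions — a smooth weight function of position applied to the
    dosages. ``interaction``: product of the mean dosage burdens of the
    first and second halves of the region. ``nonlinear``: sine of a regional
    burden. The noise is scaled so var(signal)/var(e) = snr.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    d = x.dosages
    if np.isnan(d).any():
        raise ValueError("impute missing dosages first")
    n, p = d.shape
    bp = np.array([v.bp_pos for v in x.variants], dtype=float)
    t = (bp - bp.min()) / max(bp.max() - bp.min(), 1.0)
    half = p // 2
    if signal == "linear":
        alpha = np.sin(2 * np.pi * t) + t
        raw = d @ alpha / p
    elif signal == "interaction":
        # centered burdens isolate the epistatic (product) term from the
        # marginal main effects of each region
        b1 = _burden(d, np.arange(half))
        b2 = _burden(d, np.arange(half, p))
        raw = (b1 - b1.mean()) * (b2 - b2.mean())
    elif signal == "nonlinear":
        b = _burden(d, np.arange(p))
        raw = np.sin(np.pi * b)
    else:
        raise ValueError(f"unknown signal kind {signal!r}")
    sig_var = raw.var()
    noise_sd = np.sqrt(sig_var / snr) if sig_var > 0 else 1.0
    y = raw + noise_sd * rng.standard_normal(n)
    if return_signal:
        return y, raw
    return y


def write_all_formats(x: GenotypeMatrix, prefix: str) -> None:
    """Write a genotype fixture in both PLINK encodings."""
    write_plink_bed(x, prefix)
    write_plink_text(x, prefix)
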