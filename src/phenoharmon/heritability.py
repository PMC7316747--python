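"""SNP heritability of case-control phenotype definitions.

Observed-scale h2 is estimated by Haseman-Elston (HE) regression of
phenotype cross-products on off-diagonal entries of a genetic
relationship matrix (GRM), with a block-jackknife standard error; an
optional single-component REML on the dense GRM is provided as a
cross-check. Observed-scale estimates convert to the liability scale
under case-control ascertainment via

    h2_liab = K^2 (1-K)^2 / (P (1-P) phi(t)^2) * h2_obs,

with K the population prevalence, P the study prevalence (case fraction)
and t = Phi^{-1}(1-K) the liability threshold. GRM SNPs pass
array-genotype QC (missingness, MAF, HWE, region masks) and greedy
sliding-window LD pruning before the GRM is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigurationError, EstimationError
from .phenodef import PhenotypeDefinition
from .simdata import Cohort


@dataclass
class H2Estimate:
    """A heritability estimate on a declared scale with its context."""

    definition: str
    scale: str  # "observed" | "liability"
    h2: float
    se: float
    K: float | None
    P: float
    n_samples: int
    m_snps: int
    estimator: str = "he"

    def __post_init__(self) -> None:
        if self.scale not in ("observed", "liability"):
            raise EstimationError(f"unknown scale {self.scale!r}")


# ---------------------------------------------------------------------------
# SNP QC and pruning


def hwe_pvalues(G: np.ndarray) -> np.ndarray:
    """Per-SNP 1-df chi-square Hardy-Weinberg test on hard-call dosages
    (NaN = missing)."""
    G = np.asarray(G, float)
    p = np.empty(G.shape[1])
    for j in range(G.shape[1]):
        g = G[:, j]
        g = g[~np.isnan(g)]
        n = len(g)
        if n == 0:
            p[j] = np.nan
            continue
        n2 = int((g == 2).sum())
        n1 = int((g == 1).sum())
        n0 = n - n1 - n2
        f = (2 * n2 + n1) / (2 * n)
        if f in (0.0, 1.0):
            p[j] = 1.0
            continue
        exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
        obs = np.array([n0, n1, n2])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        p[j] = stats.chi2.sf(chi2, 1)
    return p


def ld_prune(
    G: np.ndarray,
    maf: np.ndarray,
    window: int = 100,
    step: int = 50,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; of a pair with r^2 > r2_max the
    lower-MAF SNP is dropped. Returns a boolean keep mask."""
    m = G.shape[1]
    keep = np.ones(m, dtype=bool)
    Gf = np.asarray(G, float)
    start = 0
    while start < m:
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        if len(idx) > 1:
            sub = Gf[:, idx]
            sub = sub - sub.mean(axis=0)
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
            sub = sub / sd
            corr2 = (sub.T @ sub / len(sub)) ** 2
            np.fill_diagonal(corr2, 0.0)
            local_keep = np.ones(len(idx), dtype=bool)
            for a in range(len(idx)):
                if not local_keep[a]:
                    continue
                for b in range(a + 1, len(idx)):
                    if local_keep[b] and corr2[a, b] > r2_max:
                        drop = a if maf[idx[a]] < maf[idx[b]] else b
                        local_keep[drop] = False
                        if drop == a:
                            break
            keep[idx[~local_keep]] = False
        if start + window >= m:
            break
        start += step
    return keep


def grm_snps_qc(
    G: np.ndarray,
    snp_meta: pd.DataFrame | None = None,
    *,
    mind: float = 0.05,
    geno: float = 0.01,
    maf_min: float = 0.10,
    hwe_alpha: float = 0.001,
    exclude_regions: list[tuple[int, int, int]] | None = None,
    prune_window: int = 100,
    prune_step: int = 50,
    prune_r2: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """QC and LD-prune SNPs for the GRM.

    Removes samples with missingness > ``mind``; SNPs with missingness >
    ``geno``, MAF < ``maf_min`` or HWE p < ``hwe_alpha``; SNPs inside any
    ``(chr, start_bp, end_bp)`` exclusion region; then prunes at r^2 >
    ``prune_r2`` in sliding windows. Returns boolean (sample_keep,
    snp_keep) masks.
    """
    Gf = np.asarray(G, float)
    n, m = Gf.shape
    miss = np.isnan(Gf)
    sample_keep = miss.mean(axis=1) <= mind
    Gf = Gf[sample_keep]
    miss = miss[sample_keep]
    snp_keep = miss.mean(axis=0) <= geno
    freq1 = np.nanmean(Gf, axis=0) / 2.0
    maf = np.minimum(freq1, 1.0 - freq1)
    snp_keep &= maf >= maf_min
    hwe_p = hwe_pvalues(Gf)
    snp_keep &= ~(hwe_p < hwe_alpha)
    if exclude_regions and snp_meta is not None:
        chrom = snp_meta["CHR"].to_numpy()
        bp = snp_meta["BP"].to_numpy()
        for c, lo, hi in exclude_regions:
            snp_keep &= ~((chrom == c) & (bp >= lo) & (bp <= hi))
    if not snp_keep.any():
        raise EstimationError("all SNPs removed by QC")
    idx = np.where(snp_keep)[0]
    pk = ld_prune(Gf[:, idx], maf[idx], prune_window, prune_step, prune_r2)
    snp_keep[idx[~pk]] = False
    if not snp_keep.any():
        raise EstimationError("all SNPs removed by pruning")
    return sample_keep, snp_keep


def build_grm(G: np.ndarray) -> np.ndarray:
    """GRM = X X^T / m with per-SNP standardization by sqrt(2 f (1-f)).

    Monomorphic SNPs are excluded (they carry no relationship
    information); missing dosages are mean-imputed before
    standardization.
    """
    Gf = np.asarray(G, float).copy()
    col_mean = np.nanmean(Gf, axis=0)
    nan_r, nan_c = np.where(np.isnan(Gf))
    Gf[nan_r, nan_c] = col_mean[nan_c]
    f = Gf.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    Gf = Gf[:, poly]
    f = f[poly]
    if Gf.shape[1] == 0:
        raise EstimationError("no polymorphic SNPs for the GRM")
    X = (Gf - 2 * f) / np.sqrt(2 * f * (1 - f))
    return (X @ X.T) / Gf.shape[1]


# ---------------------------------------------------------------------------
# estimators


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(X)
    r = y - q @ (q.T @ y)
    sd = r.std()
    if sd <= 0:
        raise EstimationError("zero phenotypic variance after covariate adjustment")
    return r / sd


def he_regression(
    y_std: np.ndarray, grm: np.ndarray, n_blocks: int = 200
) -> tuple[float, float]:
    """Haseman-Elston: slope of y_i y_j on GRM_ij over pairs i<j, with a
    sample-block jackknife SE (blocks of contiguous samples)."""
    n = len(y_std)
    if grm.shape != (n, n):
        raise EstimationError("phenotype length does not match the GRM")
    A = np.asarray(grm, float)
    y = y_std
    # full sums over i<j, via rows minus the diagonal
    Ay = A @ y
    r1 = Ay * y - np.diag(A) * y**2  # per-sample sum over j != i of A_ij y_i y_j
    rowsq = (A**2).sum(axis=1) - np.diag(A) ** 2
    S1 = r1.sum() / 2.0
    S2 = rowsq.sum() / 2.0
    if S2 <= 0:
        raise EstimationError("GRM has no off-diagonal variation")
    slope = S1 / S2

    n_blocks = int(min(n_blocks, n))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    thetas = []
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        sl = slice(lo, hi)
        # pairs touching the block: sum of r over the block double-counts
        # within-block pairs, so add those back once
        sub = A[sl, sl]
        yb = y[sl]
        w1 = (yb @ sub @ yb - np.diag(sub) @ yb**2) / 2.0
        w2 = ((sub**2).sum() - (np.diag(sub) ** 2).sum()) / 2.0
        S1_del = S1 - r1[sl].sum() + w1
        S2_del = S2 - rowsq[sl].sum() + w2
        if S2_del > 0:
            thetas.append(S1_del / S2_del)
    thetas = np.asarray(thetas)
    nb = len(thetas)
    se = float(np.sqrt((nb - 1) / nb * ((thetas - thetas.mean()) ** 2).sum()))
    return float(slope), se


def reml_h2(y_std: np.ndarray, grm: np.ndarray) -> tuple[float, float]:
    """Single-component REML-style estimate by direct likelihood
    maximization on the GRM eigenbasis (curvature SE)."""
    n = len(y_std)
    vals, vecs = np.linalg.eigh(np.asarray(grm, float))
    yt = vecs.T @ y_std

    def negll(h2: float) -> float:
        d = h2 * vals + (1 - h2)
        d = np.maximum(d, 1e-9)
        sigma2 = float((yt**2 / d).mean())
        return 0.5 * (np.log(d).sum() + n * np.log(sigma2))

    res = optimize.minimize_scalar(negll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    h2 = float(res.x)
    eps = 1e-4
    h2c = min(max(h2, eps), 1 - eps)
    curv = (negll(h2c + eps) - 2 * negll(h2c) + negll(h2c - eps)) / eps**2
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else float("nan")
    return h2, se


def estimate_h2_observed(
    phenotype: np.ndarray,
    grm: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    definition: str = "",
    estimator: str = "he",
    n_blocks: int = 200,
) -> H2Estimate:
    """Observed-scale SNP heritability of a 0/1 phenotype.

    The phenotype is covariate-residualized and standardized; the HE slope
    (default) or REML variance fraction is the estimate. ``P`` records the
    case fraction of the raw phenotype.
    """
    y = np.asarray(phenotype, float)
    if y.std() <= 0:
        raise EstimationError("zero phenotypic variance")
    P = float(y.mean()) if set(np.unique(y)) <= {0.0, 1.0} else float("nan")
    y_std = _residualize(y, covariates)
    if estimator == "he":
        h2, se = he_regression(y_std, grm, n_blocks)
    elif estimator == "reml":
        h2, se = reml_h2(y_std, grm)
    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    return H2Estimate(
        definition=definition,
        scale="observed",
        h2=h2,
        se=se,
        K=None,
        P=P,
        n_samples=len(y),
        m_snps=0,  # caller fills in when the SNP count is known
        estimator=estimator,
    )


# ---------------------------------------------------------------------------
# liability conversion and comparison


def liability_factor(K: float, P: float) -> float:
    """Observed -> liability conversion factor
    K^2 (1-K)^2 / (P (1-P) phi(t)^2) with t = Phi^{-1}(1-K)."""
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise EstimationError("K and P must be in (0, 1)")
    t = stats.norm.isf(K)
    return float(K**2 * (1 - K) ** 2 / (P * (1 - P) * stats.norm.pdf(t) ** 2))


def liability_transform(est: H2Estimate, K: float, P: float | None = None) -> H2Estimate:
    """Convert an observed-scale estimate to the liability scale.

    P defaults to the estimate's recorded study prevalence. The SE scales
    by the same (estimate-independent) factor.
    """
    if est.scale != "observed":
        raise EstimationError("liability_transform expects an observed-scale estimate")
    if P is None:
        P = est.P
    c = liability_factor(K, P)
    return H2Estimate(
        definition=est.definition,
        scale="liability",
        h2=est.h2 * c,
        se=est.se * c,
        K=K,
        P=P,
        n_samples=est.n_samples,
        m_snps=est.m_snps,
        estimator=est.estimator,
    )


def compare_h2(a: H2Estimate, b: H2Estimate) -> tuple[float, float]:
    """Two-sample z test for a difference between independent heritability
    estimates on the same scale: (h2_a - h2_b)/sqrt(se_a^2 + se_b^2)."""
    if a.scale != b.scale:
        raise EstimationError(f"scale mismatch: {a.scale} vs {b.scale}")
    stat = (a.h2 - b.h2) / np.hypot(a.se, b.se)
    p = 2.0 * stats.norm.sf(abs(stat))
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# cohort-level convenience


def h2_for_definition(
    cohort: Cohort,
    definition: PhenotypeDefinition,
    K: float,
    *,
    n_pcs: int = 10,
    estimator: str = "he",
    n_blocks: int = 200,
    qc: bool = True,
    exclude_regions: list[tuple[int, int, int]] | None = None,
) -> H2Estimate:
    """QC + GRM + HE (or REML) + liability conversion for one phenotype
    definition on a simulated cohort, with sex and PC covariates."""
    from .assoc import compute_pcs

    ids = np.concatenate([definition.case_ids, definition.control_ids])
    G = cohort.genotype_rows(ids)
    y = np.concatenate([np.ones(definition.n_cases), np.zeros(definition.n_controls)])
    if qc:
        sample_keep, snp_keep = grm_snps_qc(
            G, cohort.snp_meta, exclude_regions=exclude_regions
        )
        G = G[np.ix_(sample_keep, snp_keep)]
        y = y[sample_keep]
        ids = ids[sample_keep]
    grm = build_grm(G)
    covs = [cohort.samples.set_index("ID").loc[ids, "SEX"].to_numpy(float)]
    if n_pcs > 0:
        covs.append(compute_pcs(G, n_pcs))
    C = np.column_stack(covs)
    est = estimate_h2_observed(
        y, grm, C, definition=definition.name, estimator=estimator, n_blocks=n_blocks
    )
    est.m_snps = G.shape[1]
    return liability_transform(est, K=K)
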