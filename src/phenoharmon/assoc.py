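"""Per-SNP association scans for case-control phenotype definitions.

The scan regresses the 0/1 case status on allele-1 dosage with fixed
covariates (sex and top principal components), the linear-model analogue
of the mixed-model scans used in large GWAS; betas on the observed 0/1
scale convert to log odds ratios via log(OR) = beta / (mu (1 - mu)) with
mu the case fraction. A per-SNP logistic option is provided for
cross-checks. Frequency filters and the genomic inflation factor follow
standard GWAS practice: test MAF >= 1%, keep MAF >= 5% downstream, and
lambda_gc = median chi-square / 0.4549.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EstimationError
from .phenodef import PhenotypeDefinition
from .simdata import Cohort

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

SUMMARY_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "FREQ1",
    "BETA", "SE", "Z", "P", "OR", "N_CASES", "N_CONTROLS",
]


@dataclass
class ScanResult:
    """Association scan output: per-SNP summary statistics for one
    phenotype definition, sorted by (CHR, BP)."""

    name: str
    records: pd.DataFrame
    lambda_gc: float
    filters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        srt = self.records.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
        self.records = srt

    @property
    def n_snps(self) -> int:
        return len(self.records)


def convert_to_logOR(beta: float | np.ndarray, mu: float) -> float | np.ndarray:
    """Observed-scale linear-model beta -> log odds ratio.

    log(OR) = beta / (mu (1 - mu)) where mu is the case fraction of the
    analyzed sample.
    """
    if not (0.0 < mu < 1.0):
        raise EstimationError(f"case fraction mu={mu} must be in (0,1)")
    return beta / (mu * (1.0 - mu))


def compute_pcs(genotypes: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotypes.

    Columns are mutually orthogonal; k=0 returns an (n, 0) array.
    """
    n, m = genotypes.shape
    if k < 0:
        raise ConfigurationError("k must be non-negative")
    if k == 0:
        return np.zeros((n, 0))
    if k >= n:
        raise ConfigurationError(f"k={k} PCs need at least k+1={k + 1} samples (got {n})")
    X = np.asarray(genotypes, float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if k > (s > 1e-10).sum():
        raise ConfigurationError(f"k={k} exceeds the rank of the genotype matrix")
    return u[:, :k] * s[:k]


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square of the observed
    p-values over the null median 0.4549."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise EstimationError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EstimationError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def maf_filter(
    records: pd.DataFrame,
    min_maf: float = 0.01,
    downstream_maf: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split records into a testing set (MAF >= min_maf) and a downstream
    set (MAF >= downstream_maf); returns (testing, downstream, counts)."""
    maf = np.minimum(records["FREQ1"], 1.0 - records["FREQ1"])
    testing = records[maf >= min_maf]
    downstream = records[maf >= downstream_maf]
    counts = {
        "n_input": len(records),
        "n_removed_testing": int((maf < min_maf).sum()),
        "n_removed_downstream": int(((maf >= min_maf) & (maf < downstream_maf)).sum()),
    }
    return testing.reset_index(drop=True), downstream.reset_index(drop=True), counts


def linear_scan(
    G: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized per-SNP linear regression of y on dosage + covariates.

    Returns a frame with BETA, SE, Z, P and a ZERO_VAR flag for SNPs whose
    dosage is constant after covariate projection (those get NaN
    statistics). Two-sided p from the normal reference.
    """
    n, m = G.shape
    if covariates is None:
        covariates = np.zeros((n, 0))
    X = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(X)
    y = np.asarray(y, float)
    y_r = y - q @ (q.T @ y)
    G_r = np.asarray(G, float) - q @ (q.T @ np.asarray(G, float))
    gtg = np.einsum("ij,ij->j", G_r, G_r)
    zero = gtg <= 1e-12
    gtg_safe = np.where(zero, 1.0, gtg)
    beta = (G_r.T @ y_r) / gtg_safe
    dof = n - X.shape[1] - 1
    if dof <= 0:
        raise EstimationError("not enough samples for the covariate model")
    rss = (y_r @ y_r) - beta**2 * gtg_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / gtg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({"BETA": beta, "SE": se, "Z": z, "P": p, "ZERO_VAR": zero})
    out.loc[zero, ["BETA", "SE", "Z", "P"]] = np.nan
    return out


def logistic_scan(G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP logistic regression (statsmodels), for cross-checks only."""
    import statsmodels.api as sm

    n, m = G.shape
    if covariates is None:
        covariates = np.zeros((n, 0))
    base = np.column_stack([np.ones(n), covariates])
    rows = []
    for j in range(m):
        g = np.asarray(G[:, j], float)
        if g.std() <= 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, True))
            continue
        X = np.column_stack([base, g])
        fit = sm.Logit(y, X).fit(disp=0)
        b, s = fit.params[-1], fit.bse[-1]
        z = b / s
        rows.append((b, s, z, 2 * stats.norm.sf(abs(z)), False))
    return pd.DataFrame(rows, columns=["BETA", "SE", "Z", "P", "ZERO_VAR"])


def association_scan(
    cohort: Cohort,
    definition: PhenotypeDefinition,
    n_pcs: int = 10,
    min_maf: float = 0.01,
    sex_covariate: bool = True,
    model: str = "linear",
) -> ScanResult:
    """Scan every SNP for association with a phenotype definition.

    Uses the definition's cases plus the shared controls (cases of other
    definitions are left out entirely). Covariates: intercept, optionally
    sex, and the top ``n_pcs`` PCs computed on the analyzed subset. SNPs
    with MAF below ``min_maf`` in the analyzed subset are not tested.
    """
    ids = np.concatenate([definition.case_ids, definition.control_ids])
    G = cohort.genotype_rows(ids)
    y = np.concatenate(
        [np.ones(definition.n_cases), np.zeros(definition.n_controls)]
    )
    mu = definition.n_cases / len(ids)
    if not (0.0 < mu < 1.0):
        raise EstimationError("definition has no cases or no controls")

    meta = cohort.snp_meta
    freq1 = np.asarray(G, float).mean(axis=0) / 2.0
    maf = np.minimum(freq1, 1.0 - freq1)
    tested = maf >= min_maf
    Gt = G[:, tested]

    covs = []
    if sex_covariate:
        sample_index = cohort.samples.set_index("ID")
        covs.append(sample_index.loc[ids, "SEX"].to_numpy(float))
    if n_pcs > 0:
        covs.append(compute_pcs(Gt, n_pcs))
    C = np.column_stack(covs) if covs else None

    scan_fn = {"linear": linear_scan, "logistic": logistic_scan}.get(model)
    if scan_fn is None:
        raise ConfigurationError(f"unknown scan model {model!r}")
    res = scan_fn(Gt, y, C)

    rec = meta.loc[tested, ["SNP", "CHR", "BP", "A1", "A2"]].reset_index(drop=True).copy()
    rec["FREQ1"] = freq1[tested]
    for col in ["BETA", "SE", "Z", "P"]:
        rec[col] = res[col].to_numpy()
    rec["OR"] = np.exp(convert_to_logOR(rec["BETA"].to_numpy(), mu))
    rec["N_CASES"] = definition.n_cases
    rec["N_CONTROLS"] = definition.n_controls
    flagged = int(res["ZERO_VAR"].sum())
    rec = rec[~res["ZERO_VAR"].to_numpy()].reset_index(drop=True)

    lam = genomic_lambda(rec["P"].to_numpy()) if len(rec) else float("nan")
    return ScanResult(
        name=definition.name,
        records=rec[SUMMARY_COLUMNS],
        lambda_gc=lam,
        filters={
            "min_maf": min_maf,
            "n_snps_input": int(len(meta)),
            "n_removed_maf": int((~tested).sum()),
            "n_zero_variance": flagged,
            "model": model,
            "n_pcs": n_pcs,
            "mu": mu,
        },
    )
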