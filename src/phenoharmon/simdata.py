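"""Synthetic case-control cohorts with multi-system subtype classification.

This module generates cohorts with the statistical structure that the rest
of the package assumes:

* LD-structured genotypes: each haplotype is a thresholded latent Gaussian
  that follows an AR(1) process within LD blocks, so allele frequency and
  LD strength are controlled independently.
* Liability-threshold subtypes: each subtype has its own disjoint set of
  causal SNPs and its own liability; a sample is a case of subtype *s* when
  its subtype-*s* liability exceeds the threshold implied by the population
  prevalence K_s. Cases are ascertained to a quota, controls are screened
  against every threshold (case-control ascertainment, P != K).
* Noisy classifiers: two or three subtyping systems observe the true
  subtype through per-system confusion matrices over
  {each subtype, 'undetermined'}; one system may emit a secondary label
  (a multi-label "phenotypic" classifier). Confusion matrices can be
  calibrated so the expected Cohen's kappa between two systems matches a
  target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, ConfigurationError, SimulationError

UNDETERMINED = "undetermined"

DEFAULT_SUBTYPES = ("CES", "LAS", "SVS")
DEFAULT_SYSTEMS = ("CCSC", "CCSP", "TOAST")


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_cases_per_subtype : int
        Ascertained case quota per subtype.
    n_controls : int
        Ascertained control quota (controls exceed no liability threshold).
    n_snps : int
        Number of biallelic SNPs.
    maf_range : (float, float)
        Allele-1 frequencies are drawn uniformly from this interval.
    ld_block_size : int
        SNPs per LD block; the latent AR(1) process resets at block (and
        chromosome) boundaries.
    ld_rho : float
        Latent-Gaussian autocorrelation between adjacent SNPs in a block.
    subtypes : tuple of str
        Subtype names (default three stroke-subtype analogues).
    h2_liability : float or dict
        SNP heritability of each subtype's liability; a scalar applies to
        every subtype.
    n_causal_per_subtype : int
        Causal SNPs per subtype; causal sets are disjoint across subtypes.
    prevalence : float or dict
        Population prevalence K_s of each subtype.
    systems : tuple of str
        Classifier system names.
    multilabel_system : str or None
        The system allowed to emit a secondary subtype label.
    secondary_label_prob : float
        Probability that the multilabel system adds a secondary label when
        its primary label is a subtype.
    target_kappa : float
        Expected Cohen's kappa between two systems; used to calibrate the
        confusion matrices when ``confusion`` is not given.
    undetermined_share : float
        Fraction of each system's misassignment mass routed to
        'undetermined' (the rest is split over the wrong subtypes).
    confusion : dict or None
        Explicit per-system confusion matrices (rows: true subtype;
        columns: subtypes + undetermined). Overrides kappa calibration.
    seed : int
        Master seed; identical config + seed gives an identical cohort.
    """

    n_cases_per_subtype: int = 400
    n_controls: int = 1200
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    h2_liability: float | dict = 0.25
    n_causal_per_subtype: int = 30
    prevalence: float | dict = 0.10
    systems: tuple[str, ...] = DEFAULT_SYSTEMS
    multilabel_system: str | None = "CCSP"
    secondary_label_prob: float = 0.25
    target_kappa: float = 0.6
    undetermined_share: float = 0.35
    confusion: dict | None = None
    seed: int = 0
    n_chromosomes: int = 4
    bp_spacing: int = 10_000
    pool_chunk: int = 4000
    max_pool: int = 400_000

    def __post_init__(self) -> None:
        if min(self.n_cases_per_subtype, self.n_controls, self.n_snps) <= 0:
            raise ConfigurationError("n_cases_per_subtype, n_controls and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError(f"maf_range must lie in (0,1): {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if self.ld_block_size <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("ld_block_size and n_chromosomes must be positive")
        if self.n_causal_per_subtype * len(self.subtypes) > self.n_snps:
            raise ConfigurationError("disjoint causal sets need n_causal_per_subtype * n_subtypes <= n_snps")
        for s in self.subtypes:
            h2, K = self.h2_of(s), self.prevalence_of(s)
            if not (0 <= h2 <= 1):
                raise ConfigurationError(f"h2_liability[{s}]={h2} outside [0,1]")
            if not (0 < K < 1):
                raise ConfigurationError(f"prevalence[{s}]={K} outside (0,1)")
        if self.multilabel_system is not None and self.multilabel_system not in self.systems:
            raise ConfigurationError(f"multilabel_system {self.multilabel_system!r} not among systems")
        if self.confusion is not None:
            for name, mat in self.confusion.items():
                validate_confusion(np.asarray(mat, float), len(self.subtypes), name)

    def h2_of(self, subtype: str) -> float:
        if isinstance(self.h2_liability, dict):
            return float(self.h2_liability[subtype])
        return float(self.h2_liability)

    def prevalence_of(self, subtype: str) -> float:
        if isinstance(self.prevalence, dict):
            return float(self.prevalence[subtype])
        return float(self.prevalence)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SubtypeEffects:
    """Causal architecture: per-subtype causal indices and effect sizes."""

    causal_idx: dict[str, np.ndarray]
    beta: dict[str, np.ndarray]


@dataclass
class Cohort:
    """An ascertained synthetic cohort.

    ``genotypes`` holds allele-1 dosages in {0,1,2} (samples x SNPs);
    ``snp_meta`` has columns SNP, CHR, BP, A1, A2, FREQ1 (FREQ1 is the
    generating, not the sample, frequency); ``samples`` has one row per
    sample with ID, SEX, STATUS ('case'/'control'), TRUE_SUBTYPE and one
    column per classifier system (multi-labels semicolon-joined, controls
    carry '.').
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    samples: pd.DataFrame
    config: SimConfig
    effects: SubtypeEffects | None = None

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["ID"].to_numpy()

    @property
    def case_ids(self) -> np.ndarray:
        return self.samples.loc[self.samples["STATUS"] == "case", "ID"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.samples.loc[self.samples["STATUS"] == "control", "ID"].to_numpy()

    def genotype_rows(self, ids: np.ndarray) -> np.ndarray:
        idx = self.samples.set_index("ID").index.get_indexer(ids)
        if np.any(idx < 0):
            raise SimulationError("unknown sample id requested")
        return self.genotypes[idx]


# ---------------------------------------------------------------------------
# genotypes


def draw_snp_meta(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = cfg.n_snps
    freq1 = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    per_chr = int(np.ceil(m / cfg.n_chromosomes))
    chrom = 1 + (np.arange(m) // per_chr)
    bp = 1 + (np.arange(m) % per_chr) * cfg.bp_spacing
    return pd.DataFrame(
        {
            "SNP": [f"snp{i + 1}" for i in range(m)],
            "CHR": chrom.astype(int),
            "BP": bp.astype(int),
            "A1": "A",
            "A2": "G",
            "FREQ1": freq1,
        }
    )


def _block_ids(cfg: SimConfig, snp_meta: pd.DataFrame) -> np.ndarray:
    # blocks never span chromosomes: key on (chr, within-chr block index)
    m = len(snp_meta)
    within = np.zeros(m, dtype=int)
    chrom = snp_meta["CHR"].to_numpy()
    for c in np.unique(chrom):
        sel = chrom == c
        within[sel] = np.arange(sel.sum()) // cfg.ld_block_size
    # unique id per (chromosome, block)
    return chrom * 10_000_000 + within


def simulate_genotypes(
    cfg: SimConfig,
    n_samples: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    snp_meta: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an ``n_samples x n_snps`` dosage matrix.

    Each of the two haplotypes per sample is an AR(1) latent Gaussian
    (autocorrelation ``ld_rho`` within an LD block, independent across
    blocks) thresholded at ``Phi^{-1}(freq1)``, so the marginal allele-1
    frequency is exactly ``freq1`` and adjacent-SNP LD rises with
    ``ld_rho``.
    """
    if n_samples is None:
        n_samples = len(cfg.subtypes) * cfg.n_cases_per_subtype + cfg.n_controls
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if snp_meta is None:
        snp_meta = draw_snp_meta(cfg, rng)
    freq1 = snp_meta["FREQ1"].to_numpy()
    thresh = stats.norm.ppf(freq1).astype(np.float32)
    blocks = _block_ids(cfg, snp_meta)
    new_block = np.ones(len(snp_meta), dtype=bool)
    new_block[1:] = blocks[1:] != blocks[:-1]

    n_hap = 2 * n_samples
    rho = np.float32(cfg.ld_rho)
    innov_sd = np.float32(np.sqrt(1.0 - cfg.ld_rho**2))
    eps = rng.standard_normal((n_hap, len(snp_meta)), dtype=np.float32)
    z = np.empty_like(eps)
    for j in range(len(snp_meta)):
        if new_block[j]:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + innov_sd * eps[:, j]
    alleles = (z < thresh[None, :]).astype(np.int8)
    geno = alleles[0::2] + alleles[1::2]
    return geno, snp_meta


# ---------------------------------------------------------------------------
# liability phenotypes


def draw_effects(cfg: SimConfig, rng: np.random.Generator) -> SubtypeEffects:
    """Draw disjoint causal SNP sets and normal effect sizes per subtype.

    Effects apply to standardized dosages and are scaled so the genetic
    variance of each liability equals that subtype's ``h2_liability``.
    """
    perm = rng.permutation(cfg.n_snps)
    causal_idx: dict[str, np.ndarray] = {}
    beta: dict[str, np.ndarray] = {}
    k = cfg.n_causal_per_subtype
    for i, s in enumerate(cfg.subtypes):
        idx = np.sort(perm[i * k : (i + 1) * k])
        causal_idx[s] = idx
        h2 = cfg.h2_of(s)
        b = rng.standard_normal(k)
        if h2 > 0:
            b *= np.sqrt(h2 / k) / b.std() if b.std() > 0 else 0.0
            # normalize the realized effect-size vector so the theoretical
            # genetic variance (sum of squared effects on standardized
            # dosages) is exactly h2
            b *= np.sqrt(h2 / np.sum(b**2))
        else:
            b[:] = 0.0
        beta[s] = b
    return SubtypeEffects(causal_idx=causal_idx, beta=beta)


def _standardize(geno: np.ndarray, freq1: np.ndarray) -> np.ndarray:
    sd = np.sqrt(2.0 * freq1 * (1.0 - freq1))
    return (geno - 2.0 * freq1) / sd


def simulate_liability_phenotypes(
    genotypes: np.ndarray,
    cfg: SimConfig,
    effects: SubtypeEffects,
    snp_meta: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign each sample a true subtype or control status.

    liability_s = sum(standardized dosage * effect) + N(0, 1 - h2_s);
    a sample is a case of subtype *s* when liability_s > Phi^{-1}(1 - K_s).
    When several thresholds are exceeded the subtype with the largest
    exceedance margin wins. Returns an object array of subtype names with
    '' for controls.
    """
    n = genotypes.shape[0]
    freq1 = snp_meta["FREQ1"].to_numpy()
    margins = np.full((n, len(cfg.subtypes)), -np.inf)
    for i, s in enumerate(cfg.subtypes):
        idx = effects.causal_idx[s]
        h2 = cfg.h2_of(s)
        g = _standardize(genotypes[:, idx], freq1[idx]) @ effects.beta[s]
        liab = g + rng.standard_normal(n) * np.sqrt(max(1.0 - h2, 0.0))
        t = stats.norm.isf(cfg.prevalence_of(s))
        margins[:, i] = liab - t
    label = np.full(n, "", dtype=object)
    exceeded = margins.max(axis=1) > 0
    winner = margins.argmax(axis=1)
    label[exceeded] = np.asarray(cfg.subtypes, dtype=object)[winner[exceeded]]
    return label


# ---------------------------------------------------------------------------
# classifiers and kappa calibration


def validate_confusion(mat: np.ndarray, n_subtypes: int, name: str = "confusion") -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.shape != (n_subtypes, n_subtypes + 1):
        raise ConfigurationError(
            f"{name}: expected shape ({n_subtypes}, {n_subtypes + 1}), got {mat.shape}"
        )
    if np.any(mat < 0):
        raise ConfigurationError(f"{name}: negative probabilities")
    rows = mat.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ConfigurationError(f"{name}: rows must sum to 1 (got {rows})")
    return mat


def symmetric_confusion(correct_prob: float, n_subtypes: int, undetermined_share: float) -> np.ndarray:
    """Confusion matrix: correct with prob c; the remaining mass goes to
    'undetermined' (share d) and uniformly to the wrong subtypes (1-d)."""
    if not (0 <= correct_prob <= 1):
        raise ConfigurationError("correct_prob outside [0,1]")
    if not (0 <= undetermined_share <= 1):
        raise ConfigurationError("undetermined_share outside [0,1]")
    c, d, S = correct_prob, undetermined_share, n_subtypes
    mat = np.zeros((S, S + 1))
    wrong = (1.0 - c) * (1.0 - d) / max(S - 1, 1)
    for t in range(S):
        mat[t, :S] = wrong
        mat[t, t] = c
        mat[t, S] = (1.0 - c) * d
    return mat


def expected_kappa(conf_a: np.ndarray, conf_b: np.ndarray, prior: np.ndarray) -> float:
    """Closed-form Cohen's kappa of two conditionally independent
    classifiers observing a true label with distribution ``prior``."""
    joint = np.einsum("t,ti,tj->ij", prior, conf_a, conf_b)
    p_o = np.trace(joint)
    p_e = joint.sum(axis=1) @ joint.sum(axis=0)
    if p_e >= 1.0:
        raise CalibrationError("degenerate joint distribution (p_e = 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def calibrate_confusion(
    target_kappa: float,
    n_subtypes: int = 3,
    *,
    prior: np.ndarray | None = None,
    undetermined_share: float = 0.35,
    tol: float = 0.01,
) -> np.ndarray:
    """Find a symmetric confusion matrix whose expected between-system
    kappa equals ``target_kappa``, by bisection on the correct-assignment
    probability.
    """
    if not (0 < target_kappa <= 1):
        raise CalibrationError("target kappa must be in (0, 1]")
    if prior is None:
        prior = np.full(n_subtypes, 1.0 / n_subtypes)
    if target_kappa == 1.0:
        mat = np.zeros((n_subtypes, n_subtypes + 1))
        mat[:, :n_subtypes] = np.eye(n_subtypes)
        return mat

    def kappa_at(c: float) -> float:
        m = symmetric_confusion(c, n_subtypes, undetermined_share)
        return expected_kappa(m, m, prior)

    lo, hi = 0.0, 1.0  # kappa is monotone in c and -> 1 as c -> 1
    if kappa_at(lo) > target_kappa:
        raise CalibrationError(f"target kappa {target_kappa} below the model's floor")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if kappa_at(mid) < target_kappa:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    mat = symmetric_confusion(c, n_subtypes, undetermined_share)
    achieved = expected_kappa(mat, mat, prior)
    if abs(achieved - target_kappa) > tol:
        raise CalibrationError(
            f"kappa target {target_kappa} unattainable (closest {achieved:.4f})"
        )
    return mat


def simulate_classifiers(
    true_subtype: np.ndarray,
    confusion: dict[str, np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw per-system observed labels for each case.

    Each system samples from its confusion row given the true subtype; the
    multilabel system additionally emits a secondary subtype label with
    probability ``secondary_label_prob`` (uniform over the other subtypes)
    when its primary label is a subtype. Labels are returned as strings,
    multi-labels semicolon-joined.
    """
    S = len(cfg.subtypes)
    labels_univ = list(cfg.subtypes) + [UNDETERMINED]
    subtype_index = {s: i for i, s in enumerate(cfg.subtypes)}
    out: dict[str, list[str]] = {}
    for system in cfg.systems:
        mat = validate_confusion(np.asarray(confusion[system], float), S, system)
        col: list[str] = []
        for t in true_subtype:
            row = mat[subtype_index[t]]
            j = rng.choice(S + 1, p=row)
            primary = labels_univ[j]
            if (
                system == cfg.multilabel_system
                and primary != UNDETERMINED
                and S > 1
                and rng.random() < cfg.secondary_label_prob
            ):
                others = [s for s in cfg.subtypes if s != primary]
                secondary = others[rng.integers(len(others))]
                col.append(f"{primary};{secondary}")
            else:
                col.append(primary)
        out[system] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cohort orchestration


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full ascertained cohort (genotypes, true subtypes,
    classifier assignments, sex).

    Samples are drawn from the population in fixed-size chunks; cases are
    kept until each subtype's quota is met and controls until theirs,
    mirroring case-control ascertainment. Raises
    :class:`SimulationError` with advice when the population pool bound is
    exhausted before quotas fill.
    """
    rng = np.random.default_rng(cfg.seed)
    snp_meta = draw_snp_meta(cfg, rng)
    effects = draw_effects(cfg, rng)

    kept_geno: dict[str, list[np.ndarray]] = {s: [] for s in cfg.subtypes}
    kept_geno["__control__"] = []
    kept_sex: dict[str, list[np.ndarray]] = {s: [] for s in cfg.subtypes}
    kept_sex["__control__"] = []
    pool_used = 0
    while True:
        need_cases = any(
            sum(len(g) for g in kept_geno[s]) < cfg.n_cases_per_subtype for s in cfg.subtypes
        )
        n_ctl = sum(len(g) for g in kept_geno["__control__"])
        if not need_cases and n_ctl >= cfg.n_controls:
            break
        if pool_used >= cfg.max_pool:
            raise SimulationError(
                "ascertainment quota not met within max_pool="
                f"{cfg.max_pool}; raise max_pool or the subtype prevalences"
            )
        chunk = min(cfg.pool_chunk, cfg.max_pool - pool_used)
        geno, _ = simulate_genotypes(cfg, chunk, rng=rng, snp_meta=snp_meta)
        labels = simulate_liability_phenotypes(geno, cfg, effects, snp_meta, rng)
        sex = rng.integers(0, 2, size=chunk)
        pool_used += chunk
        for s in cfg.subtypes:
            sel = labels == s
            if sel.any():
                kept_geno[s].append(geno[sel])
                kept_sex[s].append(sex[sel])
        sel = labels == ""
        if sel.any():
            kept_geno["__control__"].append(geno[sel])
            kept_sex["__control__"].append(sex[sel])

    geno_rows, sex_rows, status, true_lab = [], [], [], []
    for s in cfg.subtypes:
        g = np.concatenate(kept_geno[s])[: cfg.n_cases_per_subtype]
        x = np.concatenate(kept_sex[s])[: cfg.n_cases_per_subtype]
        if len(g) < cfg.n_cases_per_subtype:  # pragma: no cover - guarded above
            raise SimulationError(f"quota for subtype {s} not met")
        geno_rows.append(g)
        sex_rows.append(x)
        status += ["case"] * len(g)
        true_lab += [s] * len(g)
    g = np.concatenate(kept_geno["__control__"])[: cfg.n_controls]
    x = np.concatenate(kept_sex["__control__"])[: cfg.n_controls]
    geno_rows.append(g)
    sex_rows.append(x)
    status += ["control"] * len(g)
    true_lab += [""] * len(g)

    genotypes = np.concatenate(geno_rows)
    sex = np.concatenate(sex_rows)
    n = genotypes.shape[0]
    samples = pd.DataFrame(
        {
            "ID": [f"S{i + 1:06d}" for i in range(n)],
            "SEX": sex.astype(int),
            "STATUS": status,
            "TRUE_SUBTYPE": [t if t else "." for t in true_lab],
        }
    )

    confusion = cfg.confusion
    if confusion is None:
        mat = calibrate_confusion(
            cfg.target_kappa,
            len(cfg.subtypes),
            undetermined_share=cfg.undetermined_share,
        )
        confusion = {sys_: mat for sys_ in cfg.systems}
    case_mask = samples["STATUS"] == "case"
    assign = simulate_classifiers(
        samples.loc[case_mask, "TRUE_SUBTYPE"].to_numpy(), confusion, cfg, rng
    )
    for system in cfg.systems:
        col = np.full(n, ".", dtype=object)
        col[case_mask.to_numpy()] = assign[system].to_numpy()
        samples[system] = col

    return Cohort(genotypes=genotypes, snp_meta=snp_meta, samples=samples, config=cfg, effects=effects)
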