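"""LD clumping, locus de-duplication and fixed-effects meta-analysis.

Clumping is greedy by significance: the most significant unassigned SNP
with p below the index threshold (1e-5) seeds a clump; unassigned SNPs
within 250 kb of the index and with r^2 > 0.05 to it join the clump;
clumps whose index reaches genome-wide significance (5e-8) are flagged.
Clumps discovered in different phenotype definitions collapse to the
lowest-p representative when their indices coincide or are nearby and in
LD. Replication pooling uses inverse-variance fixed-effects weights
(w = 1/se^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; raises on zero
    variance."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    if a.shape != b.shape:
        raise EstimationError("dosage vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise EstimationError("zero-variance dosage vector: r^2 undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


class LDSource:
    """r^2 lookup backed by a genotype matrix with a SNP-id index.

    Pairs with no LD information (a SNP absent from the matrix) are
    treated as unlinked and recorded in ``missing_pairs``.
    """

    def __init__(self, genotypes: np.ndarray, snp_ids: list[str]):
        self._G = np.asarray(genotypes, float)
        self._idx = {s: j for j, s in enumerate(snp_ids)}
        self.missing_pairs: list[tuple[str, str]] = []

    def r2(self, snp_a: str, snp_b: str) -> float:
        ja, jb = self._idx.get(snp_a), self._idx.get(snp_b)
        if ja is None or jb is None:
            self.missing_pairs.append((snp_a, snp_b))
            return 0.0
        a, b = self._G[:, ja], self._G[:, jb]
        if a.std() == 0 or b.std() == 0:
            self.missing_pairs.append((snp_a, snp_b))
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class Clump:
    """One clump: an index SNP plus the SNPs it absorbed."""

    index_snp: str
    chr: int
    bp: int
    p: float
    members: list[str] = field(default_factory=list)
    definition: str = ""
    genome_wide: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)


def clump(
    scan_records: pd.DataFrame,
    ld_source: LDSource,
    *,
    index_alpha: float = 1e-5,
    window_kb: float = 250.0,
    r2_min: float = 0.05,
    gw_alpha: float = 5e-8,
    definition: str = "",
) -> list[Clump]:
    """Greedy-by-significance clumping of a scan.

    All SNPs with p < ``index_alpha`` are candidate indices; processing by
    ascending p, each unassigned candidate seeds a clump and absorbs every
    unassigned SNP (any p) within ``window_kb`` on the same chromosome
    with r^2 > ``r2_min`` to the index.
    """
    rec = scan_records.reset_index(drop=True)
    assigned = np.zeros(len(rec), dtype=bool)
    order = rec.sort_values(["P", "SNP"], kind="mergesort").index
    clumps: list[Clump] = []
    window_bp = window_kb * 1000.0
    for i in order:
        if assigned[i] or rec.loc[i, "P"] >= index_alpha:
            continue
        assigned[i] = True
        idx_snp = rec.loc[i, "SNP"]
        c = Clump(
            index_snp=str(idx_snp),
            chr=int(rec.loc[i, "CHR"]),
            bp=int(rec.loc[i, "BP"]),
            p=float(rec.loc[i, "P"]),
            definition=definition,
            genome_wide=bool(rec.loc[i, "P"] < gw_alpha),
        )
        near = (
            (rec["CHR"] == c.chr)
            & (np.abs(rec["BP"] - c.bp) <= window_bp)
            & ~assigned
        )
        for j in rec.index[near]:
            if ld_source.r2(str(idx_snp), str(rec.loc[j, "SNP"])) > r2_min:
                c.members.append(str(rec.loc[j, "SNP"]))
                assigned[j] = True
        clumps.append(c)
    return clumps


def dedupe_clumps(
    clumps: list[Clump],
    *,
    merge_kb: float = 250.0,
    ld_source: LDSource | None = None,
    r2_min: float = 0.05,
) -> list[Clump]:
    """Collapse clumps from different definitions to unique loci.

    Two clumps merge when their index SNPs coincide, or lie within
    ``merge_kb`` on the same chromosome and (when an LD source is given)
    have r^2 > ``r2_min``. The lowest-p representative is kept; its
    ``members`` gains the provenance of the absorbed indices.
    """
    ordered = sorted(clumps, key=lambda c: (c.p, c.index_snp))
    kept: list[Clump] = []
    for c in ordered:
        merged = False
        for k in kept:
            if c.index_snp == k.index_snp:
                merged = True
            elif c.chr == k.chr and abs(c.bp - k.bp) <= merge_kb * 1000.0:
                if ld_source is None or ld_source.r2(c.index_snp, k.index_snp) > r2_min:
                    merged = True
            if merged:
                if c.index_snp != k.index_snp:
                    k.members = list(k.members) + [c.index_snp]
                break
        if not merged:
            kept.append(
                Clump(
                    index_snp=c.index_snp,
                    chr=c.chr,
                    bp=c.bp,
                    p=c.p,
                    members=list(c.members),
                    definition=c.definition,
                    genome_wide=c.genome_wide,
                )
            )
    return kept


def bonferroni_threshold(alpha: float = 0.05, n_snps: int = 1, n_lookups: int = 1) -> float:
    """alpha / (n_snps * n_lookups): the replication p-value threshold for
    looking up several SNPs in several GWAS."""
    if n_snps <= 0 or n_lookups <= 0:
        raise EstimationError("counts must be positive")
    if not (0 < alpha <= 1):
        raise EstimationError("alpha must be in (0, 1]")
    return alpha / (n_snps * n_lookups)


@dataclass
class MetaResult:
    """Fixed-effects inverse-variance pooled estimate."""

    snp: str
    beta: float
    se: float
    z: float
    p: float
    betas: np.ndarray
    ses: np.ndarray
    weights: np.ndarray


def meta_fixed(betas, ses, snp: str = "") -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis of >= 2 studies.

    pooled beta = sum(w_i b_i)/sum(w_i), w_i = 1/se_i^2;
    pooled se = 1/sqrt(sum w_i); z and two-sided p from the pooled values.
    """
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if b.shape != s.shape or b.ndim != 1:
        raise EstimationError("betas and ses must be 1-d arrays of equal length")
    if len(b) < 2:
        raise EstimationError("meta-analysis needs at least two studies")
    if np.any(s <= 0):
        raise EstimationError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(snp=snp, beta=beta, se=se, z=float(z), p=p, betas=b, ses=s, weights=w)


def clumps_to_frame(clumps: list[Clump]) -> pd.DataFrame:
    rows = [
        (
            c.index_snp,
            c.chr,
            c.bp,
            c.p,
            c.n_members,
            ";".join(c.members) if c.members else ".",
            c.definition or ".",
            int(c.genome_wide),
        )
        for c in clumps
    ]
    return pd.DataFrame(
        rows,
        columns=["INDEX_SNP", "CHR", "BP", "P", "N_MEMBERS", "MEMBERS", "DEFINITION", "GENOME_WIDE"],
    )
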