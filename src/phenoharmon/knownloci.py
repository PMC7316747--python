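"""Lookup of externally reported index SNPs across phenotype definitions.

Given a list of reported index SNPs (with their effect alleles), the
odds ratios of every phenotype definition are harmonized to the reported
effect allele (1/OR when the alleles are swapped; strand-ambiguous A/T
and C/G SNPs are flagged for removal), collected into a SNP-by-definition
OR matrix, and the number of times a focal definition shows the most
extreme OR (largest |log OR|) is tested against the equal-chance null
with an exact two-sided binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError, HarmonizationError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_ambiguous(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (palindromic) SNPs: A/T or C/G."""
    a1, a2 = a1.upper(), a2.upper()
    return _COMPLEMENT.get(a1) == a2


def harmonize_or(
    or_value: float,
    a1: str,
    a2: str,
    reference_effect_allele: str,
    *,
    remove_ambiguous: bool = True,
) -> float:
    """Harmonize an odds ratio to a reference effect allele.

    OR unchanged when A1 matches the reference allele; 1/OR when A2
    matches (equivalently, the beta sign flips). Ambiguous A/T and C/G
    SNPs raise by default because strand cannot be resolved.
    """
    if or_value <= 0:
        raise HarmonizationError(f"odds ratio must be positive, got {or_value}")
    ref = reference_effect_allele.upper()
    a1u, a2u = a1.upper(), a2.upper()
    if remove_ambiguous and is_ambiguous(a1u, a2u):
        raise HarmonizationError(f"ambiguous (palindromic) SNP alleles {a1}/{a2}")
    if ref == a1u:
        return float(or_value)
    if ref == a2u:
        return float(1.0 / or_value)
    raise HarmonizationError(
        f"reference allele {reference_effect_allele} not in {{{a1}, {a2}}}"
    )


def harmonize_record(record: pd.Series, reference_effect_allele: str) -> pd.Series:
    """Harmonize a summary-statistic record (OR, BETA, Z, FREQ1 fields) to
    a reference effect allele; sign-flips beta/z and mirrors FREQ1 when
    alleles are swapped."""
    out = record.copy()
    ref = reference_effect_allele.upper()
    out["OR"] = harmonize_or(record["OR"], record["A1"], record["A2"], ref)
    if ref == str(record["A2"]).upper():
        for col in ("BETA", "Z"):
            if col in out:
                out[col] = -out[col]
        if "FREQ1" in out:
            out["FREQ1"] = 1.0 - out["FREQ1"]
        out["A1"], out["A2"] = record["A2"], record["A1"]
    return out


@dataclass
class ORMatrix:
    """Index SNPs x phenotype definitions, harmonized odds ratios.

    ``df`` is indexed by SNP id with one column per definition name plus
    a SUBTYPE column tagging the subtype each SNP was reported in;
    missing cells are NaN and are excluded from extremeness counting.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        ors = self.df.drop(columns=["SUBTYPE"], errors="ignore")
        vals = ors.to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise EstimationError("all odds ratios must be positive")

    @property
    def definitions(self) -> list[str]:
        return [c for c in self.df.columns if c != "SUBTYPE"]


def build_or_matrix(
    index_snps: pd.DataFrame,
    scans: dict[str, "pd.DataFrame"],
) -> ORMatrix:
    """Look up index SNPs in a set of scan record frames.

    ``index_snps`` needs columns SNP, EFFECT_ALLELE, SUBTYPE; ``scans``
    maps definition name -> records frame (SNP, A1, A2, OR...). SNPs
    missing from a scan, with mismatched alleles, or strand-ambiguous get
    NaN in that cell.
    """
    cols: dict[str, list[float]] = {name: [] for name in scans}
    for _, row in index_snps.iterrows():
        for name, rec in scans.items():
            hit = rec[rec["SNP"] == row["SNP"]]
            if len(hit) != 1:
                cols[name].append(np.nan)
                continue
            try:
                cols[name].append(
                    harmonize_or(
                        float(hit["OR"].iloc[0]),
                        str(hit["A1"].iloc[0]),
                        str(hit["A2"].iloc[0]),
                        str(row["EFFECT_ALLELE"]),
                    )
                )
            except HarmonizationError:
                cols[name].append(np.nan)
    df = pd.DataFrame(cols, index=index_snps["SNP"].to_numpy())
    df["SUBTYPE"] = index_snps["SUBTYPE"].to_numpy()
    return ORMatrix(df=df)


def count_most_extreme(matrix: ORMatrix, focal: str) -> tuple[int, int]:
    """(successes, trials) for the focal definition being most extreme.

    A trial is one index SNP with at least two non-missing ORs including
    the focal one; success when the focal |log OR| is strictly the
    maximum (ties count as failure).
    """
    if focal not in matrix.definitions:
        raise EstimationError(f"unknown focal definition {focal!r}")
    k = n = 0
    ors = matrix.df[matrix.definitions]
    for _, row in ors.iterrows():
        vals = row.dropna()
        if focal not in vals.index or len(vals) < 2:
            continue
        n += 1
        dist = np.abs(np.log(vals.to_numpy(float)))
        focal_dist = abs(np.log(float(vals[focal])))
        others = dist[[i for i, c in enumerate(vals.index) if c != focal]]
        if focal_dist > others.max():
            k += 1
    return k, n


def binomial_extremeness_test(k: int, n: int, p0: float = 0.2) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method): the
    probability mass of all outcomes no more likely than the observed
    one, under success probability p0."""
    if not (0 <= k <= n) or n <= 0:
        raise EstimationError(f"invalid counts k={k}, n={n}")
    if not (0 < p0 <= 1):
        raise EstimationError(f"invalid null probability {p0}")
    if p0 == 1.0:
        return 1.0 if k == n else 0.0
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
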