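"""Cross-definition overlap of significant SNP sets.

Two scans are compared over a sweep of absolute z-score thresholds
(0 to 3 in steps of 0.1): at each threshold Z the significant set is
{SNP : |z| > Z}, and the comparison reports the Jaccard index of the two
sets plus the Pearson correlation of the z-scores over the shared
(both-significant) SNPs. z-scores are beta/se, deliberately not
mean-centered so the direction of effect is preserved. An overall Jaccard
index generalizes to five scans: |significant in all| / |significant in
any|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import ScanResult
from .exceptions import EstimationError

DEFAULT_THRESHOLDS = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 1)


def zscores(scan: ScanResult) -> pd.Series:
    """Per-SNP z = beta/se, indexed by SNP id; rows with se <= 0 are
    rejected."""
    rec = scan.records
    ok = rec["SE"] > 0
    return pd.Series(
        rec.loc[ok, "BETA"].to_numpy() / rec.loc[ok, "SE"].to_numpy(),
        index=rec.loc[ok, "SNP"],
        name="Z",
    )


def significant_set(z: pd.Series, Z: float) -> set:
    """SNPs with |z| strictly greater than Z."""
    if Z < 0:
        raise EstimationError("threshold Z must be non-negative")
    return set(z.index[np.abs(z.to_numpy()) > Z])


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; 1.0 when both sets are empty (self-comparison
    limit, documented convention)."""
    union = set_a | set_b
    if not union:
        return 1.0
    return len(set_a & set_b) / len(union)


def pearson_shared(z_a: pd.Series, z_b: pd.Series, shared: set) -> tuple[float, bool]:
    """Pearson r of the two z-score vectors over the shared SNPs.

    Returns (r, defined); fewer than two shared SNPs or a zero-variance
    vector gives (nan, False).
    """
    ids = sorted(shared)
    if len(ids) < 2:
        return float("nan"), False
    a = z_a.loc[ids].to_numpy()
    b = z_b.loc[ids].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return float("nan"), False
    return float(np.corrcoef(a, b)[0, 1]), True


def overlap_curve(
    scan_a: ScanResult,
    scan_b: ScanResult,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Jaccard / Pearson / shared count over a z-threshold sweep.

    Scans are inner-joined on SNP id (the comparison runs only on SNPs
    present in both). Columns: Z, JACCARD, PEARSON, N_SHARED, DEFINED.
    """
    z_a, z_b = zscores(scan_a), zscores(scan_b)
    common = z_a.index.intersection(z_b.index)
    if len(common) == 0:
        raise EstimationError("scans share no SNPs")
    z_a, z_b = z_a.loc[common], z_b.loc[common]
    rows = []
    for Z in thresholds:
        sa, sb = significant_set(z_a, Z), significant_set(z_b, Z)
        shared = sa & sb
        r, defined = pearson_shared(z_a, z_b, shared)
        rows.append((float(Z), jaccard(sa, sb), r, len(shared), defined))
    return pd.DataFrame(rows, columns=["Z", "JACCARD", "PEARSON", "N_SHARED", "DEFINED"])


def overall_jaccard(scans: list[ScanResult], Z: float) -> float:
    """|SNPs significant in every scan| / |significant in any scan| on the
    shared SNP universe."""
    if not scans:
        raise EstimationError("need at least one scan")
    zs = [zscores(s) for s in scans]
    common = zs[0].index
    for z in zs[1:]:
        common = common.intersection(z.index)
    if len(common) == 0:
        raise EstimationError("scans share no SNPs")
    sets = [significant_set(z.loc[common], Z) for z in zs]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    if not union:
        return 1.0
    return len(inter) / len(union)
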