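"""Readers and writers for every on-disk format the pipeline touches.

All files are tab-delimited text with a header row; lines starting with
'#' are stamp/comment lines and are skipped on read. Floats are written
with a fixed '%.10g' format so that write -> read -> write round-trips
byte-identically. Coordinates are 1-based; distances are in base pairs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import SUMMARY_COLUMNS, ScanResult, genomic_lambda
from .exceptions import FormatError
from .phenodef import AssignmentTable, PhenotypeDefinition
from .simdata import Cohort, SimConfig

FLOAT_FMT = "%.10g"

REQUIRED_SUMMARY = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE"]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc


def _to_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw != "")
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad][:5]]  # +2: header + 1-based
        raise FormatError(f"{path}: malformed numeric value in column {col} at line(s) {', '.join(lines)}")
    return out.to_numpy(float)


def write_stamp(path: Path, stamp: str | None) -> None:
    if stamp:
        text = path.read_text()
        path.write_text(f"# {stamp}\n{text}")


# ---------------------------------------------------------------------------
# summary statistics


def write_summary_stats(scan: ScanResult, path, stamp: str | None = None) -> None:
    path = Path(path)
    scan.records[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_stamp(path, stamp)


def read_summary_stats(path, name: str | None = None) -> ScanResult:
    """Read a summary-statistics TSV into a :class:`ScanResult`.

    Required columns: SNP CHR BP A1 A2 BETA SE. Z, P are recomputed when
    absent; a missing OR is recomputed from BETA and the case fraction
    when N_CASES/N_CONTROLS are present. A file with OR but no BETA gets
    BETA back-computed from log(OR) * mu(1-mu) and is flagged in
    ``filters``.
    """
    path = Path(path)
    df = _read_tsv(path)
    flags: dict = {}
    has_or = "OR" in df.columns
    has_beta = "BETA" in df.columns
    if not has_beta and has_or and {"N_CASES", "N_CONTROLS"} <= set(df.columns):
        df["BETA"] = np.nan
        flags["beta_backcomputed"] = True
    missing = [c for c in REQUIRED_SUMMARY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df["SNP"][df["SNP"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicated SNP id(s): {', '.join(map(str, dup[:10]))}")

    out = pd.DataFrame({"SNP": df["SNP"]})
    out["CHR"] = _to_float(df, "CHR", path).astype(int)
    out["BP"] = _to_float(df, "BP", path).astype(int)
    out["A1"] = df["A1"]
    out["A2"] = df["A2"]
    for col, default in [("FREQ1", np.nan), ("N_CASES", np.nan), ("N_CONTROLS", np.nan)]:
        out[col] = _to_float(df, col, path) if col in df.columns else default
    if "SE" in df.columns:
        out["SE"] = _to_float(df, "SE", path)
    mu = np.nan
    if out["N_CASES"].notna().all() and out["N_CONTROLS"].notna().all():
        mu = out["N_CASES"] / (out["N_CASES"] + out["N_CONTROLS"])
    if flags.get("beta_backcomputed"):
        or_vals = _to_float(df, "OR", path)
        out["BETA"] = np.log(or_vals) * mu * (1.0 - mu)
    else:
        out["BETA"] = _to_float(df, "BETA", path)
    out["Z"] = _to_float(df, "Z", path) if "Z" in df.columns else out["BETA"] / out["SE"]
    if "P" in df.columns:
        out["P"] = _to_float(df, "P", path)
    else:
        from scipy import stats

        out["P"] = 2.0 * stats.norm.sf(np.abs(out["Z"]))
    if has_or:
        out["OR"] = _to_float(df, "OR", path)
    elif np.isscalar(mu) and np.isnan(mu):
        out["OR"] = np.nan
        flags["or_unavailable_no_mu"] = True
    else:
        out["OR"] = np.exp(out["BETA"] / (mu * (1.0 - mu)))
        flags["or_recomputed"] = True
    ok_p = out["P"].dropna()
    lam = genomic_lambda(ok_p.to_numpy()) if len(ok_p) else float("nan")
    return ScanResult(
        name=name or path.stem,
        records=out[SUMMARY_COLUMNS],
        lambda_gc=lam,
        filters=flags,
    )


# ---------------------------------------------------------------------------
# cohort tables


def write_phenotypes(cohort: Cohort, path, stamp: str | None = None) -> None:
    """Sample table: ID SEX STATUS TRUE_SUBTYPE + one column per system
    (multi-labels semicolon-joined; controls carry '.')."""
    path = Path(path)
    cohort.samples.to_csv(path, sep="\t", index=False)
    write_stamp(path, stamp)


def read_assignment_table(
    path,
    systems: tuple[str, ...],
    subtypes: tuple[str, ...],
) -> AssignmentTable:
    df = _read_tsv(Path(path))
    for col in ("ID", "STATUS", *systems):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    cases = df[df["STATUS"] == "case"].reset_index(drop=True)
    controls = df.loc[df["STATUS"] == "control", "ID"].to_numpy()
    return AssignmentTable(
        df=cases[["ID", *systems]],
        systems=tuple(systems),
        subtypes=tuple(subtypes),
        controls=controls,
    )


def write_snp_meta(cohort: Cohort, path, stamp: str | None = None) -> None:
    path = Path(path)
    cohort.snp_meta.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_stamp(path, stamp)


def write_dosages(cohort: Cohort, path, stamp: str | None = None) -> None:
    """Samples x SNPs dosage matrix; first column ID, then one integer
    column per SNP id."""
    path = Path(path)
    df = pd.DataFrame(cohort.genotypes, columns=cohort.snp_meta["SNP"])
    df.insert(0, "ID", cohort.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    write_stamp(path, stamp)


def read_dosages(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (sample_ids, genotype matrix, snp_ids)."""
    df = _read_tsv(Path(path))
    if "ID" not in df.columns:
        raise FormatError(f"{path}: dosage matrix must have an ID column")
    ids = df["ID"].to_numpy()
    snps = [c for c in df.columns if c != "ID"]
    G = df[snps].astype(int).to_numpy()
    if not np.isin(G, [0, 1, 2]).all():
        raise FormatError(f"{path}: dosages must be 0, 1 or 2")
    return ids, G.astype(np.int8), snps


def write_vcf(cohort: Cohort, path) -> None:
    """Minimal unphased-GT VCF export (REF = A2, ALT = A1, so the GT alt
    count equals the allele-1 dosage)."""
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    ids = list(cohort.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(cohort.snp_meta["CHR"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        meta = cohort.snp_meta
        for j in range(len(meta)):
            row = meta.iloc[j]
            gts = "\t".join(gt_map[int(g)] for g in cohort.genotypes[:, j])
            fh.write(
                f"{row['CHR']}\t{row['BP']}\t{row['SNP']}\t{row['A2']}\t{row['A1']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# analysis products


def write_definition(defn: PhenotypeDefinition, path, stamp: str | None = None) -> None:
    """Two-column membership file: ID, ROLE (case/control)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "ID": np.concatenate([defn.case_ids, defn.control_ids]),
            "ROLE": ["case"] * defn.n_cases + ["control"] * defn.n_controls,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    write_stamp(path, stamp)


def write_count_table(table: pd.DataFrame, path, stamp: str | None = None) -> None:
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="DEFINITION")
    write_stamp(path, stamp)


def write_h2_estimates(estimates: list, path, stamp: str | None = None) -> None:
    path = Path(path)
    rows = [
        (e.definition, e.scale, e.h2, e.se, e.K if e.K is not None else np.nan, e.P, e.n_samples, e.m_snps)
        for e in estimates
    ]
    pd.DataFrame(rows, columns=["DEFINITION", "SCALE", "H2", "SE", "K", "P", "N", "M"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    write_stamp(path, stamp)


def write_overlap_curve(curve: pd.DataFrame, path, stamp: str | None = None) -> None:
    path = Path(path)
    curve.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_stamp(path, stamp)


def write_clumps(clumps: list, path, stamp: str | None = None) -> None:
    from .clumpmeta import clumps_to_frame

    path = Path(path)
    clumps_to_frame(clumps).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_stamp(path, stamp)


def write_meta_results(results: list, path, stamp: str | None = None) -> None:
    path = Path(path)
    rows = []
    for r in results:
        row = {"SNP": r.snp, "BETA": r.beta, "SE": r.se, "Z": r.z, "P": r.p}
        for i, (b, s) in enumerate(zip(r.betas, r.ses), start=1):
            row[f"BETA{i}"] = b
            row[f"SE{i}"] = s
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    write_stamp(path, stamp)


def read_index_snps(path) -> pd.DataFrame:
    """Index-SNP list: SNP CHR BP EFFECT_ALLELE SUBTYPE [SOURCE_OR]."""
    df = _read_tsv(Path(path))
    for col in ("SNP", "EFFECT_ALLELE", "SUBTYPE"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    return df


# ---------------------------------------------------------------------------
# configuration


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_sim_config(d: dict) -> SimConfig:
    known = {f.name for f in SimConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise FormatError(f"unknown simulate key(s): {sorted(unknown)}")
    d = dict(d)
    for key in ("maf_range", "subtypes", "systems"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)
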