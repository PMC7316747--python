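"""End-to-end pipeline orchestration.

A single YAML/dict configuration with per-stage sections drives
simulate -> define -> scan -> h2 -> overlap -> known-loci -> clump ->
meta. Per-stage seeds derive from the master seed by stable hashing so a
stage is reproducible in isolation; every output file is stamped with the
config hash and seed, and all cross-stage data flows through files in the
output directory.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clumpmeta, heritability, knownloci, overlap, phenodef
from .exceptions import ConfigurationError, PhenoharmonError
from .io import (
    config_hash,
    load_sim_config,
    write_clumps,
    write_count_table,
    write_definition,
    write_dosages,
    write_h2_estimates,
    write_meta_results,
    write_overlap_curve,
    write_phenotypes,
    write_snp_meta,
    write_summary_stats,
)
from .phenodef import SET_KINDS
from .simdata import simulate_cohort

log = logging.getLogger("phenoharmon")

STAGES = ("simulate", "define", "scan", "h2", "overlap", "known_loci", "clump", "meta")
TOP_LEVEL_KEYS = {"seed", "out", "log_level", *STAGES}

STAGE_KEYS = {
    "define": {"kinds", "systems"},
    "scan": {"n_pcs", "min_maf", "kinds", "model"},
    "h2": {"K", "n_pcs", "estimator", "n_blocks", "qc", "kinds"},
    "overlap": {"focal_kind", "z_max", "z_step"},
    "known_loci": {"index_file", "focal_kind", "p0"},
    "clump": {"index_alpha", "window_kb", "r2_min", "gw_alpha", "merge_kb", "kinds"},
    "meta": {"subtype", "kind", "top_n"},
    "simulate": None,  # validated by SimConfig itself
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return int((master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1))


def validate_config(config: dict) -> dict:
    unknown = set(config) - TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
    for stage, keys in STAGE_KEYS.items():
        section = config.get(stage, {})
        if not isinstance(section, dict):
            raise ConfigurationError(f"section {stage!r} must be a mapping")
        if keys is not None:
            bad = set(section) - keys
            if bad:
                raise ConfigurationError(f"unknown key(s) in section {stage!r}: {sorted(bad)}")
    # cross-stage preconditions checked before anything runs
    if "h2" in config and "K" not in config["h2"]:
        raise ConfigurationError("h2 stage requires the population prevalence 'K'")
    load_sim_config(config.get("simulate", {}))
    return config


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> Path:
    """Run every configured stage; returns the artifact directory.

    Any stage error aborts with the stage name in the message; outputs of
    completed stages persist.
    """
    config = validate_config(dict(config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(seed if seed is not None else config.get("seed", 0))
    chash = config_hash({**config, "seed": master_seed})
    stamp = f"phenoharmon config={chash} seed={master_seed}"
    manifest: dict = {"config_hash": chash, "seed": master_seed, "stages": {}}

    state: dict = {}
    stage = "?"
    try:
        for stage in STAGES:
            t0 = time.monotonic()
            _run_stage(stage, config, state, outdir, master_seed, stamp)
            manifest["stages"][stage] = {"seconds": round(time.monotonic() - t0, 3)}
            log.info("stage %s done in %.2fs", stage, manifest["stages"][stage]["seconds"])
    except PhenoharmonError as exc:
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PhenoharmonError(f"stage {stage!r} failed: {exc}") from exc

    manifest["filters"] = state.get("filters", {})
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _scan_kinds(config: dict, systems: tuple[str, ...]) -> list[str]:
    return list(config.get("scan", {}).get("kinds", list(systems) + list(SET_KINDS)))


def _run_stage(stage, config, state, outdir, master_seed, stamp) -> None:
    if stage == "simulate":
        cfg = load_sim_config(config.get("simulate", {}))
        cfg = cfg.replace(seed=stage_seed(master_seed, "simulate"))
        cohort = simulate_cohort(cfg)
        state["cohort"] = cohort
        write_phenotypes(cohort, outdir / "phenotypes.tsv", stamp)
        write_snp_meta(cohort, outdir / "snps.tsv", stamp)
        write_dosages(cohort, outdir / "dosages.tsv", stamp)

    elif stage == "define":
        cohort = state["cohort"]
        sec = config.get("define", {})
        systems = tuple(sec.get("systems", cohort.config.systems))
        table = phenodef.AssignmentTable.from_cohort(cohort)
        kinds = sec.get("kinds", list(systems) + list(SET_KINDS))
        defs = {}
        for st in cohort.config.subtypes:
            for kind in kinds:
                d = phenodef.build_definition(table, st, kind, systems)
                defs[d.name] = d
                write_definition(d, outdir / f"definition_{d.name}.tsv", stamp)
        write_count_table(phenodef.case_count_table(table, systems), outdir / "case_counts.tsv", stamp)
        state["table"] = table
        state["definitions"] = defs

    elif stage == "scan":
        cohort = state["cohort"]
        sec = config.get("scan", {})
        kinds = _scan_kinds(config, cohort.config.systems)
        scans = {}
        for st in cohort.config.subtypes:
            for kind in kinds:
                d = state["definitions"][f"{st}-{kind}"]
                res = assoc.association_scan(
                    cohort,
                    d,
                    n_pcs=int(sec.get("n_pcs", 10)),
                    min_maf=float(sec.get("min_maf", 0.01)),
                    model=sec.get("model", "linear"),
                )
                scans[res.name] = res
                write_summary_stats(res, outdir / f"scan_{res.name}.tsv", stamp)
        state["scans"] = scans
        state.setdefault("filters", {})["scan"] = {k: v.filters for k, v in scans.items()}

    elif stage == "h2":
        if "h2" not in config:
            return
        cohort = state["cohort"]
        sec = config["h2"]
        kinds = sec.get("kinds", _scan_kinds(config, cohort.config.systems))
        ests = []
        for st in cohort.config.subtypes:
            for kind in kinds:
                d = state["definitions"][f"{st}-{kind}"]
                ests.append(
                    heritability.h2_for_definition(
                        cohort,
                        d,
                        K=float(sec["K"]),
                        n_pcs=int(sec.get("n_pcs", 10)),
                        estimator=sec.get("estimator", "he"),
                        n_blocks=int(sec.get("n_blocks", 200)),
                        qc=bool(sec.get("qc", True)),
                    )
                )
        write_h2_estimates(ests, outdir / "h2_estimates.tsv", stamp)
        state["h2"] = ests

    elif stage == "overlap":
        cohort = state["cohort"]
        sec = config.get("overlap", {})
        focal = sec.get("focal_kind", "intersect")
        scans = state["scans"]
        kinds = _scan_kinds(config, cohort.config.systems)
        rows = []
        for st in cohort.config.subtypes:
            fname = f"{st}-{focal}"
            if fname not in scans:
                continue
            for kind in kinds:
                if kind == focal:
                    continue
                other = f"{st}-{kind}"
                if other not in scans:
                    continue
                curve = overlap.overlap_curve(scans[fname], scans[other])
                write_overlap_curve(curve, outdir / f"overlap_{fname}_vs_{other}.tsv", stamp)
            five = [
                scans[f"{st}-{k}"]
                for k in list(cohort.config.systems) + ["intersect", "union"]
                if f"{st}-{k}" in scans
            ]
            if len(five) >= 2:
                rows.append((st, overlap.overall_jaccard(five, 3.0)))
        if rows:
            pd.DataFrame(rows, columns=["SUBTYPE", "OVERALL_JACCARD_Z3"]).to_csv(
                outdir / "overall_jaccard.tsv", sep="\t", index=False, float_format="%.10g"
            )

    elif stage == "known_loci":
        cohort = state["cohort"]
        sec = config.get("known_loci", {})
        focal = sec.get("focal_kind", "intersect")
        scans = state["scans"]
        if sec.get("index_file"):
            from .io import read_index_snps

            index = read_index_snps(sec["index_file"])
        else:
            # no external list: take each subtype's top SNP from the union
            # scan as the index SNP (demonstration lookup)
            rows = []
            for st in cohort.config.subtypes:
                uname = f"{st}-union"
                if uname not in scans:
                    continue
                rec = scans[uname].records
                top = rec.loc[rec["P"].idxmin()]
                rows.append((top["SNP"], top["CHR"], top["BP"], top["A1"], st))
            index = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "EFFECT_ALLELE", "SUBTYPE"])
        results = []
        for st in cohort.config.subtypes:
            sub_index = index[index["SUBTYPE"] == st]
            if not len(sub_index):
                continue
            sub_scans = {
                name.split("-", 1)[1]: s.records
                for name, s in scans.items()
                if name.startswith(f"{st}-") and not name.endswith("symmetric_difference")
            }
            if focal not in sub_scans:
                continue
            mat = knownloci.build_or_matrix(sub_index, sub_scans)
            mat.df.to_csv(outdir / f"or_matrix_{st}.tsv", sep="\t", index_label="SNP", float_format="%.10g")
            k, n = knownloci.count_most_extreme(mat, focal)
            if n:
                p0 = float(sec.get("p0", 1.0 / len(sub_scans)))
                results.append((st, k, n, knownloci.binomial_extremeness_test(k, n, p0)))
        if results:
            pd.DataFrame(results, columns=["SUBTYPE", "K", "N", "P_BINOMIAL"]).to_csv(
                outdir / "known_loci_extremeness.tsv", sep="\t", index=False, float_format="%.10g"
            )

    elif stage == "clump":
        cohort = state["cohort"]
        sec = config.get("clump", {})
        scans = state["scans"]
        ld = clumpmeta.LDSource(cohort.genotypes, list(cohort.snp_meta["SNP"]))
        all_clumps = []
        for name, s in scans.items():
            cl = clumpmeta.clump(
                s.records,
                ld,
                index_alpha=float(sec.get("index_alpha", 1e-5)),
                window_kb=float(sec.get("window_kb", 250.0)),
                r2_min=float(sec.get("r2_min", 0.05)),
                gw_alpha=float(sec.get("gw_alpha", 5e-8)),
                definition=name,
            )
            all_clumps.extend(cl)
        write_clumps(all_clumps, outdir / "clumps.tsv", stamp)
        unique = clumpmeta.dedupe_clumps(
            all_clumps, merge_kb=float(sec.get("merge_kb", 250.0)), ld_source=ld
        )
        write_clumps(unique, outdir / "clumps_unique.tsv", stamp)
        state["clumps"] = unique

    elif stage == "meta":
        # split-half discovery/replication demonstration on one definition
        cohort = state["cohort"]
        sec = config.get("meta", {})
        st = sec.get("subtype", cohort.config.subtypes[0])
        kind = sec.get("kind", "intersect")
        d = state["definitions"].get(f"{st}-{kind}")
        if d is None:
            return
        halves = []
        for parity in (0, 1):
            half = phenodef.PhenotypeDefinition(
                name=f"{d.name}-half{parity}",
                kind=d.kind,
                subtype=d.subtype,
                case_ids=d.case_ids[parity::2],
                control_ids=d.control_ids[parity::2],
            )
            halves.append(assoc.association_scan(cohort, half, n_pcs=0))
        top_n = int(sec.get("top_n", 3))
        disc = halves[0].records.nsmallest(top_n, "P")
        results = []
        rep_idx = halves[1].records.set_index("SNP")
        for _, row in disc.iterrows():
            if row["SNP"] not in rep_idx.index:
                continue
            rep = rep_idx.loc[row["SNP"]]
            results.append(
                clumpmeta.meta_fixed(
                    [row["BETA"], rep["BETA"]], [row["SE"], rep["SE"]], snp=row["SNP"]
                )
            )
        if results:
            write_meta_results(results, outdir / f"meta_{st}-{kind}.tsv", stamp)

    else:  # pragma: no cover
        raise ConfigurationError(f"unknown stage {stage}")
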