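"""End-to-end pipeline: simulate/load -> harmonize -> standardize ->
classify -> AOO -> range stats -> phylogenetic dispersion -> report.

Every stage is a pure function of (inputs, config, seed); rerunning with
the same config and seed reproduces every artifact byte for byte. The
manifest records input hashes, the config echo, the seed and per-stage row
counts, and suffices to reproduce a run. The JSON-lines log deliberately
carries no wall-clock timestamps so that logs are reproducible too.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aoo import clean_occurrences, partition_aoo_all
from .classify import (classification_table, classify_all, continuum_counts,
                       country_summary, family_coverage, global_threat_share,
                       prevalence)
from .config import RunConfig
from .errors import ConfigError
from .phylo import METRICS, permutation_dispersion_test
from .stats import (bland_altman, classify_compensation, ma_regression,
                    paired_wilcoxon, pct_threatened_histogram)
from .synthetic import (generate_world, inject_name_noise,
                        load_countries_geojson, write_world)
from .taxonomy import (apply_exclusions, apply_mapping, harmonize_names,
                       mapping_table, species_from_checklist)
from .threat import default_crosswalk, standardize_table

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def _jsonsafe(x):
    if isinstance(x, dict):
        return {k: _jsonsafe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonsafe(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if not np.isfinite(x) else x
    return x


def _load_inputs(config: RunConfig, out_dir: Path, events: list):
    if config.synthetic is not None:
        world = generate_world(config.synthetic, grid=config.grid)
        if config.synonym_rate > 0 or config.hybrid_rate > 0:
            world = inject_name_noise(world, config.synonym_rate,
                                      config.hybrid_rate, seed=config.seed)
        paths = write_world(world, out_dir / "inputs")
        events.append({"stage": "simulate", "n_species": config.synthetic.n_species,
                       "n_occurrences": len(world.occurrences)})
        tables = {
            "checklist": world.checklist,
            "naturalizations": world.naturalizations,
            "national_statuses": world.national_statuses,
            "global_statuses": world.global_statuses,
            "occurrences": world.occurrences,
            "countries": world.countries,
        }
        return tables, world.family_tree, list(world.apomictic_genera), paths
    paths = {k: Path(v) for k, v in config.inputs.items()}
    tables = {
        "checklist": pd.read_csv(paths["checklist"]),
        "naturalizations": pd.read_csv(paths["naturalizations"]),
        "national_statuses": pd.read_csv(paths["national_statuses"]),
        "global_statuses": pd.read_csv(paths["global_statuses"]),
        "occurrences": pd.read_csv(paths["occurrences"]),
        "countries": load_countries_geojson(paths["countries"]),
    }
    tree = Path(paths["family_tree"]).read_text().strip()
    apomictic = []
    if "apomictic_genera" in config.inputs:
        apomictic = [ln.strip() for ln in
                     Path(config.inputs["apomictic_genera"]).read_text().splitlines()
                     if ln.strip()]
    events.append({"stage": "load", "inputs": {k: str(v) for k, v in paths.items()}})
    return tables, tree, apomictic, paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out_dir = Path(config.out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not config.overwrite:
        raise ConfigError(f"output directory {out_dir} is not empty "
                          f"(pass overwrite to allow)")
    out_dir.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []
    tables, tree, apomictic, input_paths = _load_inputs(config, out_dir, events)

    # ---- harmonization ----
    raw_names = pd.concat([
        tables["naturalizations"]["speciesName"],
        tables["national_statuses"]["speciesName"],
        tables["global_statuses"]["speciesName"],
        tables["occurrences"]["scientificName"],
    ]).drop_duplicates().tolist()
    mappings = harmonize_names(raw_names, tables["checklist"])
    mapping_df = mapping_table(mappings)
    mapping_df.to_csv(out_dir / "harmonization_report.csv", index=False)
    n_unmatched = int((mapping_df["matchKind"] == "unmatched").sum())
    events.append({"stage": "harmonize", "n_raw_names": len(raw_names),
                   "n_unmatched": n_unmatched})
    naturalizations = apply_mapping(tables["naturalizations"], mappings, "speciesName")
    national = apply_mapping(tables["national_statuses"], mappings, "speciesName")
    global_st = apply_mapping(tables["global_statuses"], mappings, "speciesName")
    occurrences = apply_mapping(tables["occurrences"], mappings, "scientificName")

    # ---- exclusions (hybrids, apomictic genera) ----
    species = species_from_checklist(tables["checklist"], set(apomictic))
    retained, excluded = apply_exclusions(species, apomictic)
    keep = {s.accepted_name for s in retained}
    naturalizations = naturalizations[naturalizations["speciesName"].isin(keep)]
    national = national[national["speciesName"].isin(keep)]
    global_st = global_st[global_st["speciesName"].isin(keep)]
    occurrences = occurrences[occurrences["scientificName"].isin(keep)]
    events.append({"stage": "exclusions", "n_retained": len(retained),
                   "n_excluded": len(excluded)})

    # ---- category standardization ----
    crosswalk = default_crosswalk()
    national = standardize_table(national, crosswalk)
    global_st = standardize_table(global_st, crosswalk)

    # ---- continuum classification & summaries ----
    classes = classify_all(naturalizations, national, config.include_nt,
                           global_statuses=global_st)
    cls_df = classification_table(classes)
    cls_df.to_csv(out_dir / "classifications.csv", index=False)
    prev = prevalence(classes, config.include_nt)
    classes_nt = classify_all(naturalizations, national, include_nt=True,
                              global_statuses=global_st)
    prev_nt = prevalence(classes_nt, include_nt=True)
    gshare = global_threat_share(classes, global_st, config.include_nt)
    gshare_nt = global_threat_share(classes, global_st, include_nt=True)
    csum = country_summary(classes, naturalizations)
    csum["table"].to_csv(out_dir / "country_summary.csv", index=False)
    fcov = family_coverage(classes, tables["checklist"])
    fcov["table"].to_csv(out_dir / "family_counts.csv", index=False)
    prevalence_report = _jsonsafe({
        "include_nt": config.include_nt,
        "continuum_counts": continuum_counts(classes),
        "prevalence": {"n_naturalized": prev.n_naturalized, "n_paradox": prev.n_paradox,
                       "pct": prev.pct_paradox, "pct_exact": prev.pct_paradox_exact},
        "prevalence_with_nt": {"n_naturalized": prev_nt.n_naturalized,
                               "n_paradox": prev_nt.n_paradox,
                               "pct": prev_nt.pct_paradox,
                               "pct_exact": prev_nt.pct_paradox_exact},
        "global_threat": {"n_naturalized": gshare.n_naturalized,
                          "n_threatened": gshare.n_paradox, "pct": gshare.pct_paradox,
                          "pct_exact": gshare.pct_paradox_exact, "n_ew": gshare.n_ew},
        "global_threat_with_nt": {"pct": gshare_nt.pct_paradox,
                                  "pct_exact": gshare_nt.pct_paradox_exact},
        "country_mean_pct": csum["mean_pct"],
        "n_countries_over_half": csum["n_countries_over_half"],
        "family_coverage_pct": fcov["pct_families_with_paradox"],
    })
    _dump_json(prevalence_report, out_dir / "prevalence.json")
    events.append({"stage": "classify", "counts": continuum_counts(classes)})

    # ---- AOO ----
    occ_clean, drops = clean_occurrences(occurrences, tables["countries"])
    parts = partition_aoo_all(occ_clean, national, naturalizations,
                              grid=config.grid, include_nt=config.include_nt)
    parts.to_csv(out_dir / "aoo_partitions.csv", index=False, float_format="%.6f")
    events.append({"stage": "aoo", "drop_counts": drops, "n_species": len(parts)})

    # ---- range statistics on paradox species ----
    paradox = set(cls_df.loc[cls_df["continuumClass"] == "paradox", "acceptedName"])
    pp = parts[parts["acceptedName"].isin(paradox)]
    hist_in = pp.loc[pp["pctNativeThreatened"].notna(), "pctNativeThreatened"]
    analysable = pp[(pp["aooNaturalized"] > 0) & (pp["aooNativeThreatened"] > 0)]
    n_excluded_zero = len(pp) - len(analysable)
    stats_report: dict = {"n_paradox": len(pp), "n_analysable": len(analysable),
                          "n_excluded_zero_aoo": n_excluded_zero}
    if len(hist_in) > 0:
        stats_report["pct_native_threatened"] = pct_threatened_histogram(hist_in)
        hist = stats_report["pct_native_threatened"]
        pd.DataFrame({"bin_low": hist["bin_edges"][:-1],
                      "bin_high": hist["bin_edges"][1:],
                      "count": hist["bin_counts"]}).to_csv(
            out_dir / "histogram.csv", index=False)
    else:
        (out_dir / "histogram.csv").write_text("bin_low,bin_high,count\n")
    if len(analysable) >= 3:
        lx = np.log10(analysable["aooNaturalized"].to_numpy())
        ly = np.log10(analysable["aooNativeThreatened"].to_numpy())
        fit = ma_regression(lx, ly, ci_level=config.stats.ci_level,
                            bootstrap=config.stats.bootstrap_ci,
                            n_bootstrap=config.stats.n_bootstrap, seed=config.seed)
        wil = paired_wilcoxon(analysable["aooNaturalized"],
                              analysable["aooNativeThreatened"],
                              zero_method=config.stats.zero_method)
        comp, pct_partial, pct_net = classify_compensation(analysable)
        ba = bland_altman(lx, ly)
        pd.DataFrame([{"acceptedName": c.accepted_name,
                       "aooNaturalized": c.aoo_naturalized,
                       "aooThreatened": c.aoo_threatened,
                       "difference": c.difference, "class": c.klass}
                      for c in comp]).to_csv(out_dir / "compensation.csv",
                                             index=False, float_format="%.6f")
        stats_report.update(_jsonsafe({
            "ma_regression": {"slope": fit.slope, "intercept": fit.intercept,
                              "ci": [fit.slope_ci_low, fit.slope_ci_high],
                              "n": fit.n, "r": fit.r, "method": fit.method},
            "wilcoxon": {"statistic": wil.statistic, "p_value": wil.p_value,
                         "n_pairs": wil.n_pairs,
                         "median_naturalized_km2": wil.median_a,
                         "median_threatened_km2": wil.median_b},
            "compensation": {"pct_partial_compensation": pct_partial,
                             "pct_net_increase": pct_net,
                             "n_ties": sum(c.klass == "tie" for c in comp)},
            "bland_altman": {"mean_difference": ba["mean_difference"],
                             "sd": ba["sd"], "limits": list(ba["limits"])},
        }))
    else:
        (out_dir / "compensation.csv").write_text(
            "acceptedName,aooNaturalized,aooThreatened,difference,class\n")
    _dump_json(_jsonsafe(stats_report), out_dir / "stats.json")
    events.append({"stage": "stats", "n_analysable": len(analysable)})

    # ---- phylogenetic dispersion ----
    trait = fcov["table"]
    phylo_report = {"family_coverage_pct": fcov["pct_families_with_paradox"],
                    "metrics": {}}
    for i, metric in enumerate(METRICS):
        try:
            res = permutation_dispersion_test(
                tree, trait, metric=metric,
                n_permutations=config.stats.n_permutations,
                seed=config.seed + i)
            phylo_report["metrics"][metric] = {
                "observed": res.observed, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "p_value": res.p_value,
                "n_permutations": res.n_permutations}
        except Exception as exc:  # degenerate traits on tiny demo worlds
            phylo_report["metrics"][metric] = {"error": str(exc)}
    _dump_json(_jsonsafe(phylo_report), out_dir / "dispersion.json")
    events.append({"stage": "phylo", "metrics": list(phylo_report["metrics"])})

    # ---- manifest & log ----
    config_echo = config.to_dict()
    # where the artifacts land is not part of the analysis identity
    config_echo.pop("out_dir", None)
    config_echo.pop("overwrite", None)
    manifest = {
        "package": "paradoxflora", "version": __version__,
        "seed": config.seed, "config": config_echo,
        "input_hashes": {k: _sha256(p) for k, p in sorted(input_paths.items())
                         if Path(p).is_file()},
        "row_counts": {
            "naturalizations": len(naturalizations), "national_statuses": len(national),
            "global_statuses": len(global_st), "occurrences_raw": len(occurrences),
            "occurrences_clean": len(occ_clean), "species_classified": len(cls_df),
            "species_with_aoo": len(parts),
        },
        "stages": [e["stage"] for e in events],
    }
    _dump_json(_jsonsafe(manifest), out_dir / "manifest.json")
    with open(out_dir / "run.log.jsonl", "w") as fh:
        for e in events:
            fh.write(json.dumps(_jsonsafe(e), sort_keys=True) + "\n")

    report = {"manifest": manifest, "prevalence": prevalence_report,
              "stats": stats_report, "dispersion": phylo_report}
    log.info("pipeline complete: %d artifacts in %s",
             len(list(out_dir.glob('*.*'))), out_dir)
    return report
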