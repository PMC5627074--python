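"""Stage orchestration: one structured config drives every scan.

Each ``run_*`` function chains the library stages (io -> methylation calls
-> asymmetry tests -> outputs) and is fully determined by (config, seed);
rerunning with the same config reproduces identical files. Defaults equal
the study parameters: epsilon = 0.01, >= 10 reads per strand, 95th
coverage percentile, 1800 bp windows with >= 8 methylated CpGs, 100
shuffles, 1% pattern-abundance floor, 1000 bootstrap resamples, alpha
0.05.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io_meth, methcall, null_shuffle, patterns, region_asym, site_asym, stat_models
from .simdata import ErrorModel

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "run_site_scan",
    "run_region_scan",
    "run_null",
    "run_patterns",
    "run_compare_groups",
]

log = logging.getLogger("hemimeth")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "results",
    "error": {"epsilon": 0.01, "delta": 0.0},
    "inputs": {"calls": None, "cytosine_report": None, "trim_bp": 0},
    "methcall": {"alpha": 0.05, "min_per_strand": 10, "coverage_quantile": 0.95},
    "site": {"alpha": 0.05},
    "region": {"window_size": 1800, "min_meth_cpgs": 8, "step": 300, "alpha": 0.05},
    "null": {"n_shuffles": 100, "mode": "hypergeometric", "scan_regions": True},
    "patterns": {"loci": {}, "min_frac": 0.01, "n_boot": 1000, "alpha": 0.05},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Merge a YAML file path or dict over the defaults."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _outdir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_params(stage: str, config: dict, keys: list[str]) -> None:
    params = {k: config[k] for k in keys if k in config}
    log.info("%s parameters: %s", stage, json.dumps(params, default=str, sort_keys=True))


def _load_units(config: dict) -> pd.DataFrame:
    inputs = config["inputs"]
    if inputs.get("cytosine_report"):
        records = io_meth.read_cytosine_report(inputs["cytosine_report"])
        units = methcall.add_levels(io_meth.cytosine_report_to_units(records))
    elif inputs.get("calls"):
        calls = io_meth.read_per_read_calls(
            inputs["calls"], trim_bp=int(inputs.get("trim_bp", 0))
        )
        units = methcall.units_from_calls(calls)
    elif isinstance(inputs.get("units"), pd.DataFrame):
        units = methcall.add_levels(inputs["units"])
    else:
        raise ConfigError("inputs.calls or inputs.cytosine_report is required")
    return units


def _called_filtered_units(config: dict) -> pd.DataFrame:
    mc = config["methcall"]
    eps = float(config["error"]["epsilon"])
    units = _load_units(config)
    units = methcall.filter_units(
        units,
        min_per_strand=int(mc["min_per_strand"]),
        coverage_quantile=float(mc["coverage_quantile"]),
    )
    return methcall.call_methylated(units, epsilon=eps, alpha=float(mc["alpha"]))


def run_site_scan(config) -> dict:
    """Unit table + BH-flagged asymmetric CpGs (Fisher per site)."""
    config = load_config(config)
    _log_params("site-scan", config, ["error", "methcall", "site"])
    out = _outdir(config)
    units = _called_filtered_units(config)
    units = site_asym.flag_asymmetric_sites(units, alpha=float(config["site"]["alpha"]))
    units.to_csv(out / "units.tsv", sep="\t", index=False)
    flagged = units[units["asymmetric"]]
    flagged.to_csv(out / "asymmetric_sites.tsv", sep="\t", index=False)
    io_meth.write_asymmetric_sites_bed(flagged, out / "asymmetric_sites.bed")
    log.info("site-scan: %d units, %d flagged", len(units), len(flagged))
    return {"units": units, "flagged": flagged, "output_dir": out}


def run_region_scan(config) -> dict:
    """Sliding-window paired-t scan; merged flagged regions + profiles."""
    config = load_config(config)
    _log_params("region-scan", config, ["error", "methcall", "region"])
    out = _outdir(config)
    units = _called_filtered_units(config)
    rg = config["region"]
    windows, regions = region_asym.region_scan(
        units,
        window_size=int(rg["window_size"]),
        min_meth_cpgs=int(rg["min_meth_cpgs"]),
        step=int(rg["step"]),
        alpha=float(rg["alpha"]),
    )
    windows.to_csv(out / "windows.tsv", sep="\t", index=False)
    regions.to_csv(out / "asymmetric_regions.tsv", sep="\t", index=False)
    profiles = [
        region_asym.region_profile(units, region)
        for region in regions.itertuples(index=False)
    ]
    if profiles:
        pd.concat(
            [p.assign(region=i) for i, p in enumerate(profiles)], ignore_index=True
        ).to_csv(out / "region_profiles.tsv", sep="\t", index=False)
    log.info("region-scan: %d windows tested, %d regions", len(windows), len(regions))
    return {"units": units, "windows": windows, "regions": regions, "output_dir": out}


def run_null(config) -> dict:
    """Strand-shuffle false-positive scan (site + region) with summary."""
    config = load_config(config)
    _log_params("null-scan", config, ["error", "methcall", "site", "region", "null"])
    out = _outdir(config)
    units = _called_filtered_units(config)
    rg = config["region"]
    per_shuffle, summary = null_shuffle.false_positive_scan(
        units,
        n_shuffles=int(config["null"]["n_shuffles"]),
        site_alpha=float(config["site"]["alpha"]),
        region_params={
            "window_size": int(rg["window_size"]),
            "min_meth_cpgs": int(rg["min_meth_cpgs"]),
            "step": int(rg["step"]),
            "alpha": float(rg["alpha"]),
        },
        seed=int(config["seed"]),
        mode=config["null"]["mode"],
        scan_regions=bool(config["null"].get("scan_regions", True)),
    )
    per_shuffle.to_csv(out / "null_per_shuffle.tsv", sep="\t", index=False)
    pd.DataFrame([summary]).to_csv(out / "null_summary.tsv", sep="\t", index=False)
    log.info("null-scan summary: %s", summary)
    return {"per_shuffle": per_shuffle, "summary": summary, "output_dir": out}


def _pattern_tables(config: dict) -> dict[str, patterns.PatternTable]:
    inputs = config["inputs"]
    if not inputs.get("calls"):
        raise ConfigError("patterns stages need inputs.calls (per-read calls)")
    calls = io_meth.read_per_read_calls(inputs["calls"], trim_bp=int(inputs.get("trim_bp", 0)))
    loci = config["patterns"]["loci"]
    if not loci:
        raise ConfigError("patterns.loci must map locus ids to cpg_positions")
    tables = {}
    for locus_id, spec in loci.items():
        tables[locus_id] = patterns.extract_patterns(
            calls,
            spec["cpg_positions"],
            min_frac=float(config["patterns"].get("min_frac", 0.01)),
            locus_id=locus_id,
        )
    return tables


def run_patterns(config) -> dict:
    """Pattern extraction, EM frequency estimates, strand/replicate models,
    bootstrap strand-difference CIs — per configured locus."""
    config = load_config(config)
    _log_params("patterns", config, ["error", "patterns"])
    out = _outdir(config)
    err = ErrorModel(**config["error"])
    results = {}
    for locus_id, table in _pattern_tables(config).items():
        table.to_tsv(out / f"{locus_id}.patterns.tsv")
        est = patterns.estimate_frequencies_em(table, err)
        est.freqs.to_csv(out / f"{locus_id}.freqs.tsv", sep="\t", index=False)
        boot = patterns.strand_difference_bootstrap(
            table, err, n_boot=int(config["patterns"]["n_boot"]), seed=int(config["seed"])
        )
        boot.to_csv(out / f"{locus_id}.strand_diff_ci.tsv", sep="\t", index=False)
        cells = stat_models.cells_from_table(table)
        model_rows = {}
        if cells["pattern"].nunique() >= 2:
            full = stat_models.fit_multinomial(cells, ["strand", "replicate"])
            no_strand = stat_models.fit_multinomial(cells, ["replicate"])
            no_rep = stat_models.fit_multinomial(cells, ["strand"])
            dd_s, df_s, p_s = stat_models.lrt_factor(full, no_strand)
            dd_r, df_r, p_r = stat_models.lrt_factor(full, no_rep)
            model_rows = {
                "locus": locus_id,
                "deviance_strand": dd_s,
                "df_strand": df_s,
                "p_strand": p_s,
                "deviance_replicate": dd_r,
                "df_replicate": df_r,
                "p_replicate": p_r,
            }
            full.wald.assign(locus=locus_id).to_csv(
                out / f"{locus_id}.wald.tsv", sep="\t", index=False
            )
            pd.DataFrame([model_rows]).to_csv(
                out / f"{locus_id}.model.tsv", sep="\t", index=False
            )
        results[locus_id] = {
            "table": table,
            "estimate": est,
            "bootstrap": boot,
            "model": model_rows,
        }
        log.info(
            "patterns %s: %d patterns, %s",
            locus_id,
            table.counts["pattern"].nunique(),
            model_rows or "no model (single pattern)",
        )
    return {"loci": results, "output_dir": out}


def run_compare_groups(config) -> dict:
    """Strand+replicate+group multinomial comparison per locus."""
    config = load_config(config)
    _log_params("compare-groups", config, ["error", "patterns"])
    out = _outdir(config)
    alpha = float(config["patterns"]["alpha"])
    results = {}
    for locus_id, table in _pattern_tables(config).items():
        cells = stat_models.cells_from_table(table)
        if cells["group"].nunique() < 2:
            raise ConfigError(f"locus {locus_id}: <2 groups present in calls")
        res = stat_models.compare_groups(cells, ["strand", "replicate", "group"], alpha=alpha)
        res["group_wald"].assign(locus=locus_id).to_csv(
            out / f"{locus_id}.group_wald.tsv", sep="\t", index=False
        )
        results[locus_id] = res
        log.info(
            "compare-groups %s: %.0f%% of patterns differ between groups",
            locus_id,
            100 * res["fraction_significant"],
        )
    return {"loci": results, "output_dir": out}
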