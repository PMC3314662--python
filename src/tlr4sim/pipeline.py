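"""End-to-end orchestration: synthetic data → differential expression →
scenario construction → pathway simulation → scenario comparison.

Every stage writes its tables to the run directory together with the
resolved configuration and seed, so a run can be regenerated byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, scenarios, sensitivity, synthetic
from .network import PeakMetrics, build_default_network, peak_metrics, simulate

log = logging.getLogger("tlr4sim")

SCENARIO_ORDER = ("base", "min_resp", "avg_resp", "max_resp")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_probes": 2000,
        "n_animals": 3,
        "baseline_mean": 8.0,
        "noise_sd": 0.25,
        "planted_effects": {},
    },
    "diffexpr": {"lowess_span": 0.3, "alpha": 0.05},
    "scenarios": {"use_reference_fixture": True, "triple_complex_rule": "product"},
    "simulation": {"t_end": 360.0, "rel_tol": 1e-8, "abs_tol": 1e-10,
                   "lps_dose": 1000.0, "model": "default", "sbml_path": None},
}


def compare_scenarios(metrics: dict[str, PeakMetrics]) -> pd.DataFrame:
    """Peak and peak-interval ratios of each scenario against the base run.

    Peak ratio is 100·H(scenario)/H(base) (percent); interval ratio is
    FWHM(scenario)/FWHM(base) (fold).  Both are invariant to rescaling the
    readout's units.
    """
    if "base" not in metrics:
        raise ValueError("base scenario metrics required")
    base = metrics["base"]
    if base.peak_height <= 0:
        raise ValueError("base peak must be positive")
    rows = []
    for name, m in metrics.items():
        interval_ratio = (m.fwhm / base.fwhm
                          if m.fwhm is not None and base.fwhm else np.nan)
        rows.append({
            "scenario": name,
            "peak_height": m.peak_height,
            "time_to_peak": m.time_to_peak,
            "fwhm": m.fwhm,
            "peak_ratio_pct": 100.0 * m.peak_height / base.peak_height,
            "interval_ratio": interval_ratio,
        })
    return pd.DataFrame(rows).set_index("scenario", drop=False)


def _merged_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in merged:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"malformed config: {path}")
    return _merged_config(cfg)


def run_pipeline(config: dict | str | Path | None, outdir, seed: int | None = None) -> Path:
    """Run every stage and write tables, comparison and logs to ``outdir``."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    # 1. synthetic paired-design data ------------------------------------
    syn = cfg["synthetic"]
    log.info("stage=synthetic n_probes=%s n_animals=%s seed=%s",
             syn["n_probes"], syn["n_animals"], cfg["seed"])
    spec = synthetic.SimulationSpec(
        n_probes=int(syn["n_probes"]), n_animals=int(syn["n_animals"]),
        baseline_mean=float(syn["baseline_mean"]), noise_sd=float(syn["noise_sd"]),
        planted_effects=dict(syn["planted_effects"]), seed=int(cfg["seed"]))
    table = synthetic.generate_intensities(spec)
    table.to_tsv(outdir / "intensities.tsv", outdir / "design.tsv")

    # 2. normalization + differential expression -------------------------
    de_cfg = cfg["diffexpr"]
    log.info("stage=diffexpr span=%s alpha=%s", de_cfg["lowess_span"], de_cfg["alpha"])
    normalized = diffexpr.lowess_normalize(table, span=float(de_cfg["lowess_span"]))
    de = diffexpr.fit_table(normalized)
    volcano = diffexpr.volcano_table(de, alpha=float(de_cfg["alpha"]))
    de_out = volcano.assign(p_raw=de["p_raw"])
    de_out[["probe_set_id", "lsmean_diff", "p_raw", "p_adj", "direction",
            "significant"]].to_csv(outdir / "diffexpr.csv", index=False)
    volcano[["probe_set_id", "lsmean_diff", "neg_log10_p_adj",
             "significant"]].to_csv(outdir / "volcano.csv", index=False)
    _maybe_plot_volcano(volcano, outdir / "volcano.png")

    # 3. scenario construction -------------------------------------------
    sc_cfg = cfg["scenarios"]
    log.info("stage=scenarios use_reference_fixture=%s", sc_cfg["use_reference_fixture"])
    if sc_cfg["use_reference_fixture"]:
        ref = synthetic.table2_fixture()
        summaries = {
            r.species: scenarios.summary_from_multipliers(
                r.r_min_resp, r.r_max_resp, r.r_avg_resp, r.sensitivity)
            for r in ref.itertuples()
            if r.species not in synthetic.COMPLEX_CONSTITUENTS
        }
        scen_table = scenarios.build_scenario_table(
            ratio_sets={}, constituent_summaries=summaries,
            sensitivities=dict(zip(ref["species"], ref["sensitivity"])),
            base_concs=dict(zip(ref["species"], ref["base_conc"])),
            triple_complex_rule=str(sc_cfg["triple_complex_rule"]))
    else:
        raise NotImplementedError(
            "ratio-derived scenarios require a species-annotated intensity table; "
            "use scenarios.ratios_from_table + build_scenario_table directly")
    scen_table.to_csv(outdir / "scenario_table.csv", index=False)

    # 4. pathway simulation across scenarios -----------------------------
    sim = cfg["simulation"]
    log.info("stage=simulation t_end=%s model=%s", sim["t_end"], sim["model"])
    metrics: dict[str, PeakMetrics] = {}
    profiles = {}
    for name in SCENARIO_ORDER:
        model = build_default_network(scen_table, scenario=name,
                                      lps_dose=float(sim["lps_dose"]))
        tc = simulate(model, t_end=float(sim["t_end"]),
                      rel_tol=float(sim["rel_tol"]), abs_tol=float(sim["abs_tol"]))
        metrics[name] = peak_metrics(tc)
        profiles[name] = tc.readout("TNF")
        time = tc.time
    prof = pd.DataFrame({"time_min": time, **profiles})
    prof.to_csv(outdir / "tnf_profiles.csv", index=False)
    _maybe_plot_profiles(prof, outdir / "tnf_profiles.png")

    # 5. sensitivity + comparison ----------------------------------------
    log.info("stage=sensitivity")
    base_model = build_default_network(scen_table, scenario="base",
                                       lps_dose=float(sim["lps_dose"]))
    report = sensitivity.sensitivity_report(
        base_model, species=list(scen_table["species"]), t_end=float(sim["t_end"]))
    report[["species", "base_conc", "sensitivity", "rank"]].to_csv(
        outdir / "sensitivity.csv", index=False)

    comparison = compare_scenarios(metrics)
    comparison.to_csv(outdir / "scenario_comparison.csv", index=False)
    log.info("stage=done outdir=%s", outdir)
    return outdir


def _maybe_plot_volcano(volcano: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort; the CSV is authoritative
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"]
    ax.scatter(volcano.loc[~sig, "lsmean_diff"], volcano.loc[~sig, "neg_log10_p_adj"],
               s=4, alpha=0.4, color="grey")
    ax.scatter(volcano.loc[sig, "lsmean_diff"], volcano.loc[sig, "neg_log10_p_adj"],
               s=8, color="crimson")
    ax.set_xlabel("lsmean difference (N − Y, log2)")
    ax.set_ylabel("−log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _maybe_plot_profiles(prof: pd.DataFrame, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in prof.columns:
        if col == "time_min":
            continue
        ax.plot(prof["time_min"], prof[col], label=col)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("TNF (molecules per cell)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
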