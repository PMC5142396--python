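"""Umbrella pipeline tying the analysis stages together.

Stage order mirrors a screening campaign: occupancy design -> picking
simulation -> (synthetic) assay reduction -> phenotyping -> cross-host
comparison.  A run is fully determined by its configuration mapping plus the
seed recorded in it; every stage writes its table atomically into the output
directory and the run log captures package version, seed and all parameter
values, so any reported number can be regenerated.

Two presets exist:

* ``study``   — the study conditions: N=148, n=66, the packaged activity
  table, both hosts compared.
* ``synthetic`` — a generated campaign (truth -> traces -> activities ->
  ranking) whose truth file makes it usable as a recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay import AssayConfig, reduce_well
from .crosshost import concordance_classes, correlation, pair_hosts
from .io import (
    HOST_BS,
    HOST_CG,
    CAMPAIGN_TABLE_CAVEAT,
    campaign_multiplicity_census,
    campaign_sp_records,
    write_csv_atomic,
)
from .occupancy import (
    LibraryDesign,
    PickPlan,
    coverage_probability,
    multiplicity_pmf,
    required_picks,
)
from .phenotype import SPRecord, normalize_by_max, rank_sps
from .simulate import empirical_relative_occurrence, replicate_campaigns
from .synth import CampaignTruth, gen_campaign, gen_traces, gen_true_activities

__all__ = ["PipelineStageError", "default_config", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def default_config(preset: str = "study", seed: int = 1, out_dir: str = "secscreen_run") -> dict:
    base = {
        "preset": preset,
        "seed": int(seed),
        "out_dir": out_dir,
        "design": {
            "library_size": 148,
            "picks": 66,
            "oversampling_factors": [3, 4],
            "target_coverage": 0.95,
            "max_multiplicity": 4,
        },
        "simulate": {"replicates": 10_000},
        "compare": {"high_threshold_pct": 50.0, "ratio_threshold": 4.0},
    }
    if preset == "synthetic":
        base["synth"] = {
            "truth_mode": "lognormal",
            "n_clones": 66,
            "n_replicates": 8,
            "replicate_cv": 0.15,
            "dilution_factor": 10.0,
            "trace_noise_sd": 0.005,
            "n_traced_clones": 8,
        }
    elif preset != "study":
        raise ValueError(f"unknown preset {preset!r}")
    return base


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - rewrapped with stage locus
                raise PipelineStageError(name, e) from e
        return wrapped
    return deco


@_stage("design")
def _run_design(cfg: dict, out: Path) -> dict:
    d = cfg["design"]
    N, n = d["library_size"], d["picks"]
    rows = [
        {"quantity": f"P(X={m})", "m": m, "value": multiplicity_pmf(n, N, m)}
        for m in range(1, d["max_multiplicity"] + 1)
    ]
    for k in d["oversampling_factors"]:
        rows.append({"quantity": f"coverage_{k}x", "m": None, "value": coverage_probability(k * N, N)})
    rows.append(
        {
            "quantity": f"required_picks_p{d['target_coverage']}",
            "m": None,
            "value": required_picks(d["target_coverage"], N),
        }
    )
    frame = pd.DataFrame(rows)
    write_csv_atomic(frame, out / "occupancy_report.csv")
    return {"occupancy_report": frame}


@_stage("simulate")
def _run_simulate(cfg: dict, out: Path) -> dict:
    d = cfg["design"]
    plan = PickPlan(n_picks=d["picks"], library_size=d["library_size"])
    library = LibraryDesign(d["library_size"])
    result = replicate_campaigns(plan, library, cfg["simulate"]["replicates"], cfg["seed"])
    write_csv_atomic(result.summary.reset_index(), out / "simulation_summary.csv")
    return {"simulation": result}


@_stage("phenotype")
def _run_phenotype_study(cfg: dict, out: Path) -> dict:
    series = {}
    for host in (HOST_CG, HOST_BS):
        records = rank_sps(normalize_by_max(campaign_sp_records(host)))
        frame = pd.DataFrame(
            {
                "sp_id": [r.sp_id for r in records],
                "host": host,
                "mean_U_per_mL": [r.mean_activity for r in records],
                "sd_U_per_mL": [r.sd_activity for r in records],
                "relative_pct": [r.relative_activity_pct for r in records],
            }
        )
        write_csv_atomic(frame, out / f"phenotype_{host}.csv")
        series[host] = records
    census = campaign_multiplicity_census()
    occ = empirical_relative_occurrence(census, n_picks=cfg["design"]["picks"])
    write_csv_atomic(
        pd.DataFrame(
            {"m": list(census), "members": list(census.values()), "relative_occurrence": list(occ.values())}
        ),
        out / "empirical_multiplicity.csv",
    )
    return {"phenotype": series, "census": census}


@_stage("compare")
def _run_compare(cfg: dict, out: Path, series: dict) -> dict:
    pairs, only_a, only_b = pair_hosts(series[HOST_CG], series[HOST_BS])
    c = cfg["compare"]
    labelled, counts = concordance_classes(
        pairs, high_threshold_pct=c["high_threshold_pct"], ratio_threshold=c["ratio_threshold"]
    )
    summary = correlation(labelled)
    frame = pd.DataFrame(
        {
            "sp_id": [p.sp_id for p in labelled],
            "rel_C_glutamicum_pct": [p.rel_host_a for p in labelled],
            "rel_B_subtilis_pct": [p.rel_host_b for p in labelled],
            "concordance_class": [p.concordance_class for p in labelled],
        }
    )
    write_csv_atomic(frame, out / "crosshost_pairs.csv")
    write_csv_atomic(
        pd.DataFrame(
            [
                {
                    "pearson_r": summary.pearson_r,
                    "spearman_rho": summary.spearman_rho,
                    "n_pairs": summary.n_pairs,
                    **{f"n_{k}": v for k, v in summary.class_counts.items()},
                }
            ]
        ),
        out / "crosshost_summary.csv",
    )
    return {"pairs": labelled, "comparison": summary, "unmatched": (only_a, only_b)}


@_stage("synthesize")
def _run_synthetic(cfg: dict, out: Path) -> dict:
    s = cfg["synth"]
    N = cfg["design"]["library_size"]
    library = LibraryDesign(N)
    truth = CampaignTruth(
        library=library,
        true_activity_per_sp=gen_true_activities(N, mode=s["truth_mode"], seed=cfg["seed"]),
        replicate_cv=s["replicate_cv"],
        seed=cfg["seed"],
    )
    table = gen_campaign(truth, s["n_clones"], s["n_replicates"])
    write_csv_atomic(table, out / "synthetic_campaign.csv")
    write_csv_atomic(
        pd.DataFrame(
            {
                "sp_id": [truth.sp_id(i) for i in range(N)],
                "true_activity_U_per_mL": truth.true_activity_per_sp,
            }
        ),
        out / "synthetic_truth.csv",
    )
    # Trace a handful of clones through the full assay reduction.
    assay_cfg = AssayConfig()
    traced = []
    for clone_id, grp in list(table.groupby("clone_id"))[: s["n_traced_clones"]]:
        a_true = truth.true_activity_per_sp[int(grp["member"].iloc[0])]
        sample, blank = gen_traces(
            a_true,
            assay_cfg,
            dilution_factor=s["dilution_factor"],
            noise_sd=s["trace_noise_sd"],
            seed=cfg["seed"] * 100_003 + int(clone_id.removeprefix("clone")),
            well_id=clone_id,
        )
        m = reduce_well(sample, blank, assay_cfg)
        traced.append(
            {
                "clone_id": clone_id,
                "true_activity_U_per_mL": a_true,
                "recovered_activity_U_per_mL": m.activity_U_per_mL,
                "slope_per_min": m.slope_per_min,
                "fit_r2": m.fit_r2,
            }
        )
    write_csv_atomic(pd.DataFrame(traced), out / "synthetic_assay_roundtrip.csv")
    records = [
        SPRecord.from_replicates(sp, "synthetic", grp["activity"].tolist())
        for sp, grp in table.groupby("sp_id")
    ]
    ranked = rank_sps(normalize_by_max(records))
    write_csv_atomic(
        pd.DataFrame(
            {
                "sp_id": [r.sp_id for r in ranked],
                "mean_U_per_mL": [r.mean_activity for r in ranked],
                "sd_U_per_mL": [r.sd_activity for r in ranked],
                "relative_pct": [r.relative_activity_pct for r in ranked],
            }
        ),
        out / "synthetic_phenotype.csv",
    )
    return {"truth": truth, "campaign": table, "ranked": ranked}


def run_pipeline(config: dict | str | Path) -> dict:
    """Run all stages for a configuration (mapping or YAML path).

    Returns the in-memory stage results; all tables are also written to
    ``config['out_dir']``.  Deterministic given config + seed.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    cfg = default_config(config.get("preset", "study"), config.get("seed", 1),
                         config.get("out_dir", "secscreen_run"))
    for key, value in config.items():
        if isinstance(value, dict) and key in cfg:
            cfg[key].update(value)
        else:
            cfg[key] = value
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    results: dict = {}
    results.update(_run_design(cfg, out))
    results.update(_run_simulate(cfg, out))
    if cfg["preset"] == "study":
        results.update(_run_phenotype_study(cfg, out))
        results.update(_run_compare(cfg, out, results["phenotype"]))
    else:
        results.update(_run_synthetic(cfg, out))

    log = {
        "secscreen_version": __version__,
        "config": cfg,
        "activity_table_caveat": CAMPAIGN_TABLE_CAVEAT if cfg["preset"] == "study" else None,
    }
    log_path = out / "run_log.yaml"
    tmp = log_path.with_suffix(".yaml.tmp")
    tmp.write_text(yaml.safe_dump(log, sort_keys=True), encoding="utf-8")
    tmp.replace(log_path)
    results["config"] = cfg
    return results
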