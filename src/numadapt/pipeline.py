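"""End-to-end pipeline: simulate -> fit -> metrics -> stats -> behavior -> report.

Each stage reads the previous stage's delimited artifacts from the output
directory and writes its own, so stages can be re-run independently;
requesting a stage whose inputs are missing raises an error naming the
stage that must run first.  All outputs carry a provenance header and the
whole pipeline is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import adaptation, stats
from .config import PipelineConfig
from .io import read_table, read_voxels, write_table, write_voxels
from .models import fit_voxels, make_tuned_grid
from .stimuli import mean_power_table
from .synth import generate_behavioral_dataset, generate_voxel_dataset

__all__ = ["STAGES", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "metrics", "stats", "behavior", "report")

#: artifact each stage needs -> the stage that produces it
_REQUIRES = {
    "fit": [("voxel_metadata.csv", "simulate")],
    "metrics": [("fits.csv", "fit")],
    "stats": [("map_examples.csv", "metrics"), ("fits.csv", "fit")],
    "report": [("map_examples.csv", "metrics"), ("stats_summary.json", "stats")],
}


def _check_inputs(stage: str, out_dir: Path) -> None:
    for artifact, producer in _REQUIRES.get(stage, []):
        if not (out_dir / artifact).exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires '{artifact}', produced by stage "
                f"'{producer}' — run that stage first"
            )


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir="numadapt_out",
    stages=None,
) -> Path:
    """Execute the requested pipeline stages in dependency order."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        stages = [s for s in STAGES if s in set(stages)]
    else:
        stages = list(STAGES)
    prov = config.provenance()
    config.to_yaml(out_dir / "config_resolved.yaml")
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("numadapt")
    root.addHandler(handler)
    prior_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        log.info("pipeline start: stages=%s seed=%d config=%s",
                 stages, config.seed, config.hash())
        log.info("resolved config: %s", config.as_dict())
        for stage in stages:
            _check_inputs(stage, out_dir)
            log.info("stage %s", stage)
            globals()[f"_stage_{stage}"](config, out_dir, prov)
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()
    return out_dir


def _power_table(config: PipelineConfig) -> dict[int, float] | None:
    if config.mode != "log_power":
        return None
    return mean_power_table(seed=config.seed, method=config.power_method)


def _stage_simulate(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    synth_cfg = config.synth
    if synth_cfg.seed != config.seed:
        import dataclasses

        synth_cfg = dataclasses.replace(synth_cfg, seed=config.seed)
    pt = _power_table(config)
    voxels, truth = generate_voxel_dataset(
        synth_cfg, hrf=config.hrf, mode=config.mode, power_table=pt
    )
    write_voxels(voxels, out_dir, prov)
    write_table(truth, out_dir / "ground_truth.csv", prov)
    if pt is not None:
        with open(out_dir / "power_table.json", "w") as fh:
            json.dump({str(k): v for k, v in pt.items()}, fh, indent=1)


def _stage_fit(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    voxels = read_voxels(out_dir)
    pt = None
    if config.mode == "log_power":
        pt_path = out_dir / "power_table.json"
        if pt_path.exists():
            with open(pt_path) as fh:
                pt = {int(k): v for k, v in json.load(fh).items()}
        else:
            pt = _power_table(config)
    fits = fit_voxels(
        voxels,
        hrf=config.hrf,
        mode=config.mode,
        power_table=pt,
        grid=make_tuned_grid(),
    )
    write_table(fits, out_dir / "fits.csv", prov)


def _stage_metrics(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    fits = read_table(out_dir / "fits.csv")
    th = config.thresholds
    selected = adaptation.select_voxels(fits, ecc_max=th.ecc_max_deg,
                                        min_r2=th.monotonic_r2)
    write_table(selected, out_dir / "selected_voxels.csv", prov)
    examples = adaptation.aggregate_map_examples(selected,
                                                 min_example_r2=th.map_example_r2)
    examples = adaptation.add_proportional_reduction(examples, drop_undefined=False)
    write_table(examples, out_dir / "map_examples.csv", prov)


def _stage_stats(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    examples = read_table(out_dir / "map_examples.csv")
    fits = read_table(out_dir / "fits.csv")
    included = examples.loc[examples["included"].astype(bool)].copy()
    summary: dict = {}

    tables = []
    for cond in ("low", "high", "changing"):
        t = stats.per_map_signed_rank(included, f"mean_slope_{cond}")
        t.insert(0, "family", f"slope_above_zero_{cond}")
        tables.append(t)
    diffs = included.assign(slope_diff=included["mean_slope_low"]
                            - included["mean_slope_high"])
    t = stats.per_map_signed_rank(diffs, "slope_diff")
    t.insert(0, "family", "slope_low_minus_high")
    tables.append(t)
    signed_rank = pd.concat(tables, ignore_index=True)
    write_table(signed_rank, out_dir / "signed_rank_tests.csv", prov)

    reductions = included.dropna(subset=["proportional_reduction"])
    anova = stats.map_effect_anova(reductions)
    write_table(anova["tukey"], out_dir / "tukey.csv", prov)
    summary["map_anova"] = {"F": anova["F"], "df": list(anova["df"]),
                            "p": anova["p"]}

    wide = reductions.pivot_table(index=["participant", "hemisphere"],
                                  columns="map_label",
                                  values="proportional_reduction")
    corr_rows = []
    maps = list(wide.columns)
    for i, a in enumerate(maps):
        for b in maps[i + 1:]:
            corr_rows.append(stats.region_correlations(
                wide[a], wide[b], map_a=a, map_b=b))
    if corr_rows:
        write_table(pd.DataFrame(corr_rows), out_dir / "map_correlations.csv",
                    prov)

    tuned_sum = stats.tuned_effect_summaries(fits)
    if not tuned_sum.empty:
        write_table(tuned_sum, out_dir / "tuned_effects.csv", prov)
        joined = tuned_sum.merge(
            reductions, on=["participant", "hemisphere", "map_label"],
            how="inner",
        )
        for metric in ("delta_r2", "pref_change_slope"):
            res = stats.region_correlations(
                joined["proportional_reduction"], joined[metric],
                metric=metric)
            summary[f"reduction_vs_{metric}"] = {
                k: res[k] for k in ("n", "r", "p", "normality_ok")}

    summary["mean_reduction_by_map"] = (
        reductions.groupby("map_label", observed=True)["proportional_reduction"]
        .mean().to_dict()
    )
    summary["n_map_examples"] = int(len(included))
    with open(out_dir / "stats_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)


def _stage_behavior(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    from .behavior import compare_pse, fit_psychometric

    b = config.behavior
    trials, truth = generate_behavioral_dataset(
        effects=b.pse_means, between_sd=b.between_sd,
        n_participants=b.n_participants, n_trials=b.n_trials,
        observer_sigma=b.observer_sigma, seed=config.seed,
        placement=b.placement,
    )
    write_table(trials, out_dir / "behavior_trials.csv", prov)
    write_table(truth, out_dir / "behavior_truth.csv", prov)
    fits = []
    for (part, cond), grp in trials.groupby(["participant", "condition"]):
        m = fit_psychometric(grp)
        fits.append({"participant": part, "condition": cond,
                     "pse": m.pse_, "sigma": m.sigma_,
                     "deviance": m.deviance_})
    fits = pd.DataFrame(fits)
    write_table(fits, out_dir / "behavior_fits.csv", prov)
    write_table(compare_pse(fits), out_dir / "behavior_tests.csv", prov)


def _stage_report(config: PipelineConfig, out_dir: Path, prov: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    examples = read_table(out_dir / "map_examples.csv")
    with open(out_dir / "stats_summary.json") as fh:
        summary = json.load(fh)
    included = examples.loc[examples["included"].astype(bool)]
    order = [m for m in ("V1", "V2", "V3", "hV4", "LO1", "LO2", "V3AB")
             if m in set(included["map_label"])]
    means = included.groupby("map_label")["proportional_reduction"].mean()
    sems = included.groupby("map_label")["proportional_reduction"].sem()

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(order, [means[m] for m in order],
           yerr=[sems[m] for m in order], color="steelblue")
    ax.set_ylabel("proportional slope reduction")
    ax.set_xlabel("visual field map")
    fig.tight_layout()
    fig.savefig(out_dir / "reduction_by_map.png", dpi=120)
    plt.close(fig)

    lines = [
        "# numadapt pipeline report",
        "",
        f"- config hash: {prov['config_hash']}, seed: {prov['seed']}",
        f"- map examples included: {summary['n_map_examples']}",
        "- map effect ANOVA: F({},{}) = {:.2f}, p = {:.3g}".format(
            summary["map_anova"]["df"][0], summary["map_anova"]["df"][1],
            summary["map_anova"]["F"], summary["map_anova"]["p"]),
        "",
        "Mean proportional slope reduction by map:",
        "",
    ]
    for m in order:
        lines.append(f"- {m}: {means[m]:.3f} +/- {sems[m]:.3f} (sem)")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
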