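"""End-to-end analysis pipeline: simulate → gate → yields → partitioning → stats.

One :class:`~cytoferm.io.PipelineConfig` drives the full run; a single
seed is spawned deterministically into per-stage streams so repeated
runs are byte-identical. Each stage writes a CSV under the configured
output directory and the run closes with a JSON summary (fold changes,
accumulation ratios, subpopulation fractions, test results, every
fitted live-gate threshold and every unimodal fallback).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, simulate, yields_stats
from .io import PipelineConfig, write_table
from .partitioning import WeakAcidParams, accumulation_ratio, intracellular_mm

log = logging.getLogger("cytoferm.pipeline")

#: Pyruvate band (g/L) reported for non-growing post-shift cultures.
PYRUVATE_PERSISTENCE_BAND = (0.13, 0.20)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name in the message."""


def _stage_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds below 2**31 for portability of stored configs
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _round_trip(frame: pd.DataFrame, decimals: int = 6) -> pd.DataFrame:
    return frame.round(decimals)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the summary dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    seeds = _stage_seeds(config.seed, 4)
    summary: dict = {"config_hash": chash, "seed": config.seed}

    # ---- stage 1: fermentation time courses (replicated per group) -------
    try:
        courses: dict[str, list[simulate.FermentationSeries]] = {}
        rng = np.random.default_rng(seeds[0])
        for group in config.groups:
            spec = simulate.phenotype(group)
            reps = [
                simulate.simulate_timecourse(
                    spec, seed=int(rng.integers(2**31)), ba0_mm=config.ba0_mm
                )
                for _ in range(config.n_replicates)
            ]
            courses[group] = reps
            write_table(
                _round_trip(reps[0].frame), outdir / f"timecourse_group{group}.csv",
                chash,
            )
        summary["t_shift_h"] = {
            g: [round(r.t_shift, 3) for r in reps] for g, reps in courses.items()
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage 'simulate-timecourses' failed: {exc}") from exc

    # ---- stage 2: cytometry simulation + gating recovery ------------------
    try:
        gate_config = gating.GateConfig(
            width_cutoff=config.width_cutoff,
            fl1_cutoff=config.fl1_cutoff,
            fsc_threshold=config.fsc_threshold,
            max_events=config.max_events,
        )
        reporter_group = "III" if "III" in config.groups else config.groups[0]
        series = courses[reporter_group][0]
        trajectory = simulate.gfp_trajectory(series)
        picks = np.linspace(0, len(trajectory) - 1, config.n_timepoints).astype(int)
        rng = np.random.default_rng(seeds[1])
        samples, times, truth_rows = [], [], []
        for idx in picks:
            row = trajectory.iloc[idx]
            spec = simulate.default_population_spec(
                live_fraction=float(row["live_fraction"]),
                gfp_pos_fraction=float(row["gfp_pos_fraction"]),
            )
            table = simulate.simulate_events(
                spec,
                n=int(config.n_events * 1.1) + 50,  # headroom for FSC trigger loss
                seed=int(rng.integers(2**31)),
                fsc_threshold=config.fsc_threshold,
                max_events=config.n_events,
            )
            samples.append(table)
            times.append(float(row["time_h"]))
            truth_rows.append(
                {
                    "time": float(row["time_h"]),
                    "true_live_fraction": float(row["live_fraction"]),
                    "true_gfp_pos_fraction": float(row["gfp_pos_fraction"]),
                }
            )
        gate_table = gating.gate_timeseries(samples, gate_config, times)
        gate_table = gate_table.merge(pd.DataFrame(truth_rows), on="time")
        write_table(_round_trip(gate_table), outdir / "gating_timeseries.csv", chash)
        for _, row in gate_table.iterrows():
            log.info(
                "t=%.1f h live-gate threshold %.1f fallback=%s",
                row["time"], row["live_gate_threshold"], row["unimodal_fallback"],
            )
        summary["gating"] = {
            "live_gate_thresholds": [round(v, 3) for v in gate_table["live_gate_threshold"]],
            "unimodal_fallbacks": [bool(v) for v in gate_table["unimodal_fallback"]],
            "frac_live": [round(v, 4) for v in gate_table["frac_live"]],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'gating' failed: {exc}") from exc

    # ---- stage 3: yields and BA mass balance ------------------------------
    try:
        rng = np.random.default_rng(seeds[2])
        yield_rows = []
        for variant, mppa_final in config.producer_variants.items():
            spec = simulate.phenotype("III", mppa_final_mm=float(mppa_final))
            for rep in range(config.n_replicates):
                course = simulate.simulate_timecourse(
                    spec, seed=int(rng.integers(2**31)), ba0_mm=config.ba0_mm
                )
                final = course.frame.iloc[-1]
                basis = (
                    config.ba0_mm
                    if config.yield_basis == "initial"
                    else config.ba0_mm - float(final["ba_mm"])
                )
                y = yields_stats.molar_yield(float(final["mppa_mm"]), basis)
                balance = yields_stats.ba_mass_balance(
                    config.ba0_mm,
                    float(final["ba_mm"]),
                    float(final["mppa_mm"]),
                    float(final["oh_mm"]),
                    biomass_bound_fraction_of_loss=0.10,
                )
                yield_rows.append(
                    {
                        "variant": variant,
                        "replicate": rep,
                        "mppa_final_mm": float(final["mppa_mm"]),
                        "molar_yield": y.molar_yield,
                        "percent": y.percent,
                        "ba_loss_fraction": balance.loss_fraction,
                        "ba_unexplained_fraction": balance.unexplained,
                    }
                )
        yields_table = pd.DataFrame(yield_rows)
        write_table(_round_trip(yields_table), outdir / "yields.csv", chash)

        mean_yields = yields_table.groupby("variant")["molar_yield"].mean()
        ref = mean_yields.iloc[0]
        summary["yields"] = {
            "mean_molar_yield": {k: round(v, 4) for k, v in mean_yields.items()},
            "fold_change_vs_first_variant": {
                k: yields_stats.fold_change(ref, v).rounded
                for k, v in mean_yields.items()
            },
        }
        # non-producing groups report zero MPPA yield
        group_yields = {}
        for group, reps in courses.items():
            finals = [float(r.frame["mppa_mm"].iloc[-1]) for r in reps]
            group_yields[group] = round(
                float(np.mean([f / config.ba0_mm for f in finals])), 4
            )
        summary["yields"]["group_mppa_yield"] = group_yields
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'yields' failed: {exc}") from exc

    # ---- stage 4: pyruvate partitioning ------------------------------------
    try:
        partition_rows = []
        for group, reps in courses.items():
            pyr_final = float(np.mean([r.frame["pyruvate_gl"].iloc[-1] for r in reps]))
            for label, ph_in in (
                ("starved", config.ph_in_starved),
                ("glucose_growth", config.ph_in_growth),
            ):
                params = WeakAcidParams(
                    pka=config.pka, ph_in=ph_in, ph_out=config.ph_out, mw=config.mw
                )
                partition_rows.append(
                    {
                        "group": group,
                        "state": label,
                        "pyruvate_extracellular_gl": pyr_final,
                        "accumulation_ratio": accumulation_ratio(params),
                        "pyruvate_intracellular_mm": intracellular_mm(
                            pyr_final, params, unit="g/L"
                        ),
                    }
                )
        partition_table = pd.DataFrame(partition_rows)
        write_table(_round_trip(partition_table), outdir / "partitioning.csv", chash)
        lo, hi = PYRUVATE_PERSISTENCE_BAND
        persistent = {
            g: bool(lo <= np.mean([r.frame["pyruvate_gl"].iloc[-1] for r in reps]) <= hi)
            for g, reps in courses.items()
        }
        summary["partitioning"] = {
            "accumulation_ratio_starved": round(
                accumulation_ratio(
                    WeakAcidParams(config.pka, config.ph_in_starved, config.ph_out)
                ),
                3,
            ),
            "accumulation_ratio_growth": round(
                accumulation_ratio(
                    WeakAcidParams(config.pka, config.ph_in_growth, config.ph_out)
                ),
                3,
            ),
            "persistent_pyruvate_flag": persistent,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'partitioning' failed: {exc}") from exc

    # ---- stage 5: statistical comparisons ----------------------------------
    try:
        # glycerol specific yield: slow growers (group II) vs the rest
        def glycerol_specific(reps):
            vals = []
            for r in reps:
                shift_rows = r.frame[r.frame["time_h"] <= r.t_shift]
                final = shift_rows.iloc[-1]
                vals.append(
                    yields_stats.specific_yield(
                        float(final["glycerol_gl"]), float(final["biomass_gdw_l"])
                    )
                )
            return vals

        stats_rows = []
        if "II" in courses and len(courses) > 1:
            x = glycerol_specific(courses["II"])
            y = [
                v
                for g, reps in courses.items()
                if g != "II"
                for v in glycerol_specific(reps)
            ]
            if config.stats_method == "mannwhitney":
                result = yields_stats.mann_whitney_exact(x, y)
            elif config.stats_method == "welch":
                result = yields_stats.welch_t(x, y)
            else:
                result = yields_stats.gated_t_test(
                    x, y, direction=config.stats_direction
                )
            stats_rows.append(
                {
                    "comparison": "glycerol_specific_yield_II_vs_rest",
                    "method": result.method,
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "sidedness": result.sidedness,
                    "passed_preconditions": result.passed_preconditions,
                }
            )
        if stats_rows:
            stats_table = pd.DataFrame(stats_rows)
            write_table(_round_trip(stats_table), outdir / "stats.csv", chash)
            summary["stats"] = [
                {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in row.items()
                }
                for row in stats_rows
            ]
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'stats' failed: {exc}") from exc

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", summary_path)
    return summary
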