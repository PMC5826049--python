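"""End-to-end reproducible runs tying the analysis stages together.

``run_pipeline`` executes the synthetic two-condition experiment —
wild-type-like (tethered, crosslinked asters), depleted (free, threefold
apparent diffusion) and an ATP-depleted-like passive condition — through
fluctuation analysis, nuclear-array regularity, depletion kinetics and
spindle-count aggregation, and returns a report with per-stage accounting.
Every stage derives its randomness from the single root seed, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluctuation, io, kinetics, nuclear_array, synthetic_data
from .config import GroundTruth, SimulationConfig

#: Default study conditions of the synthetic experiment. The tethered
#: wild-type regime uses relaxation time tau = 20 s; depleted embryos show
#: about threefold-increased apparent diffusion and ATP-depleted (azide)
#: about fivefold-reduced; both are expressed relative to the wild-type
#: apparent D at the 1 s acquisition lag.
DEFAULT_TETHER_TAU_S = 20.0
DEFAULT_CONTROL_TRUE_D = 0.01  # µm²/s
DEPLETED_FOLD = 3.0
AZIDE_FOLD = 1.0 / 5.0

#: Nuclear-array disorder of the two conditions, as fractions of the
#: lattice spacing. The control jitter of 0.25 reproduces the reported
#: control embryo topology (about half the interior nuclei hexagonal,
#: most of the rest with 5 or 7 neighbors); depleted embryos get stronger
#: jitter plus packing defects (fused / mispositioned nuclei).
CONTROL_NOISE_FRACTION = 0.25
DEPLETED_NOISE_FRACTION = 0.40
DEPLETED_DEFECT_RATE = 0.15


def tethered_apparent_D(true_D: float, tau: float, dt: float) -> float:
    """Apparent diffusion of a tethered particle at lag dt.

    Over one frame the tethered (Ornstein-Uhlenbeck) mean squared
    displacement is 2*D*tau*(1-exp(-dt/tau)) per axis, so the lag-dt
    apparent diffusion is D*tau*(1-exp(-dt/tau))/dt < D.
    """
    return true_D * tau * (1.0 - math.exp(-dt / tau)) / dt


def condition_truths(
    control_true_D: float = DEFAULT_CONTROL_TRUE_D,
    tau: float = DEFAULT_TETHER_TAU_S,
    dt: float = 1.0,
) -> dict[str, tuple[GroundTruth, bool]]:
    """Ground truths for the three fluctuation conditions.

    Returns condition name -> (truth, tethered flag). The depleted and
    azide conditions are free with true_D chosen so their apparent
    diffusion at lag dt is respectively DEPLETED_FOLD above and AZIDE_FOLD
    of the tethered control's.
    """
    d_app = tethered_apparent_D(control_true_D, tau, dt)
    return {
        "control": (
            GroundTruth(true_D=control_true_D, relaxation_time=tau),
            True,
        ),
        "depleted": (GroundTruth(true_D=DEPLETED_FOLD * d_app), False),
        "azide": (GroundTruth(true_D=AZIDE_FOLD * d_app), False),
    }


def default_config(seed: int = 0) -> dict:
    return {
        "seed": int(seed),
        "fluctuation": {
            "n_particles": 300,
            "dt": 1.0,
            "duration": 220.0,
            "drift_window_s": 60.0,
            "lag": 1,
            "control_true_D": DEFAULT_CONTROL_TRUE_D,
            "tau": DEFAULT_TETHER_TAU_S,
        },
        "nuclei": {
            "n_embryos": 3,
            "n_rows": 12,
            "n_cols": 12,
            "lattice_spacing": 5.0,
            "control_noise_fraction": CONTROL_NOISE_FRACTION,
            "depleted_noise_fraction": DEPLETED_NOISE_FRACTION,
            "depleted_defect_rate": DEPLETED_DEFECT_RATE,
        },
        "kinetics": {
            "half_life_s": 1800.0,
            "dt": 60.0,
            "duration": 3540.0,
            "noise_sd": 0.02,
            "plateau_fraction": 0.0,
        },
        "counts": {
            "n_embryos": 3,
            "spindles_per_embryo": 50,
            # abnormal-spindle rates per genotype after protease injection:
            # embryos with only the cleavable motor, heterozygous embryos
            # retaining a wild-type allele, and wild type
            "abnormal_rates": {
                "cleavable_only": 0.75,
                "heterozygous": 0.10,
                "wild_type": 0.0,
            },
        },
    }


def _fluctuation_stage(seed: int, cfg: dict) -> dict:
    results = {}
    truths = condition_truths(cfg["control_true_D"], cfg["tau"], cfg["dt"])
    for offset, (name, (truth, tethered)) in enumerate(truths.items()):
        sim_cfg = SimulationConfig(
            seed=seed + offset, dt=cfg["dt"], duration=cfg["duration"]
        )
        traj = synthetic_data.simulate_trajectories(
            sim_cfg, truth, cfg["n_particles"], tethered=tethered, label=name
        )
        res = fluctuation.analyze_trajectories(
            traj, drift_window_s=cfg["drift_window_s"], lag=cfg["lag"]
        )
        results[name] = res
    comparison = fluctuation.compare_conditions(
        results["control"].D, results["depleted"].D
    )
    return {
        "per_condition": {
            name: {
                "mean_D_um2_per_s": res.mean_D,
                "box": dataclasses.asdict(res.box),
                "n_analyzed": len(res.D),
                "n_excluded": len(res.excluded),
            }
            for name, res in results.items()
        },
        "fold_change_depleted_vs_control": comparison.fold_change,
        "t_statistic": comparison.t_statistic,
        "p_value": comparison.p_value,
        "ranking_lowest_first": [
            name
            for name, _ in sorted(
                results.items(), key=lambda kv: kv[1].mean_D
            )
        ],
        "_results": results,
    }


def _nuclei_stage(seed: int, cfg: dict) -> dict:
    spacing = cfg["lattice_spacing"]
    conditions = {
        "control": GroundTruth(
            lattice_spacing=spacing,
            positional_noise_sd=cfg["control_noise_fraction"] * spacing,
            defect_rate=0.0,
        ),
        "depleted": GroundTruth(
            lattice_spacing=spacing,
            positional_noise_sd=cfg["depleted_noise_fraction"] * spacing,
            defect_rate=cfg["depleted_defect_rate"],
        ),
    }
    per_embryo: dict[str, list] = {}
    for c_off, (name, truth) in enumerate(conditions.items()):
        per_embryo[name] = []
        for e in range(cfg["n_embryos"]):
            sim_cfg = SimulationConfig(seed=seed + 100 * (c_off + 1) + e)
            arr = synthetic_data.generate_nuclear_array(
                sim_cfg, truth, cfg["n_rows"], cfg["n_cols"], label=f"{name}-{e}"
            )
            per_embryo[name].append(nuclear_array.regularity(arr))
    comparison = nuclear_array.compare_regularity(
        per_embryo["control"], per_embryo["depleted"]
    )
    return {
        "per_condition": {
            name: {
                "mean_proportions": {
                    b: float(np.mean([r.proportions[b] for r in results]))
                    for b in nuclear_array.NEIGHBOR_BINS
                },
                "mean_sigma_over_mu": float(
                    np.mean([r.sigma_over_mu for r in results])
                ),
                "n_interior_total": int(sum(r.n_interior for r in results)),
                "n_embryos": len(results),
            }
            for name, results in per_embryo.items()
        },
        "comparison": {
            key: dataclasses.asdict(c) for key, c in comparison.items()
        },
        "_per_embryo": per_embryo,
    }


def _kinetics_stage(seed: int, cfg: dict) -> dict:
    sim_cfg = SimulationConfig(seed=seed, dt=cfg["dt"], duration=cfg["duration"])
    truth = GroundTruth(true_half_life=cfg["half_life_s"])
    series = synthetic_data.simulate_decay_series(
        sim_cfg,
        truth,
        plateau_fraction=cfg["plateau_fraction"],
        noise_sd=cfg["noise_sd"],
    )
    fit = kinetics.fit_half_life(series)
    return {
        "n_points": len(series),
        "fit": {
            "i0": fit.i0,
            "i_inf": fit.i_inf,
            "k_per_s": fit.k,
            "t_half_s": fit.t_half,
            "t_half_min": None if fit.t_half is None else fit.t_half / 60.0,
            "converged": fit.converged,
        },
        "_series": series,
    }


def _counts_stage(seed: int, cfg: dict) -> dict:
    out: dict = {"per_genotype": {}}
    tables = []
    for g_off, (genotype, rate) in enumerate(cfg["abnormal_rates"].items()):
        counts = synthetic_data.simulate_spindle_counts(
            seed + 1000 * (g_off + 1),
            n_embryos=cfg["n_embryos"],
            spindles_per_embryo=cfg["spindles_per_embryo"],
            abnormal_rate=rate,
        )
        counts = counts.assign(genotype=genotype)
        tables.append(counts)
        out["per_genotype"][genotype] = nuclear_array.aggregate_proportions(counts)
    out["_counts"] = pd.concat(tables, ignore_index=True)
    return out


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run every stage on seeded synthetic data and assemble the report.

    When ``outdir`` is given, stage tables and the JSON report are written
    there (trajectories, per-nucleus tables, decay series, report.json).
    """
    config = default_config() if config is None else config
    seed = int(config["seed"])
    fluct = _fluctuation_stage(seed, config["fluctuation"])
    nuc = _nuclei_stage(seed, config["nuclei"])
    kin = _kinetics_stage(seed, config["kinetics"])
    cnt = _counts_stage(seed, config["counts"])

    report = {
        "config": config,
        "seed": seed,
        "fluctuation": {k: v for k, v in fluct.items() if not k.startswith("_")},
        "nuclei": {k: v for k, v in nuc.items() if not k.startswith("_")},
        "kinetics": {k: v for k, v in kin.items() if not k.startswith("_")},
        "spindle_counts": {k: v for k, v in cnt.items() if not k.startswith("_")},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_decay_series(kin["_series"], outdir / "decay_series.csv")
        cnt["_counts"].to_csv(outdir / "spindle_counts.csv", index=False)
        for name, res in fluct["_results"].items():
            pd.DataFrame(
                {
                    "particle_id": res.particle_ids,
                    "D_um2_per_s": res.D,
                    "n_steps": res.n_steps,
                }
            ).to_csv(outdir / f"fluctuation_{name}.csv", index=False, float_format="%.9g")
        io.write_json(report, outdir / "report.json")
    return report
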