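"""Simulation batteries and figure-replication recipes.

A battery runs the two-trial task for a grid of second-stimulus angles with
many random seeds per angle, decodes the behavioral response at requested
times in the second delay, and summarizes the serial-dependence tuning with
a DoG fit and bootstrap CI per decode time.

Seeding: the per-simulation seed for angle index k, repetition j is drawn
from ``numpy.random.SeedSequence([master_seed, k, j])`` (masked to 31 bits),
so results are independent of batch partitioning or worker count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import bootstrap_peak_to_peak, fit_dog, signed_circular_error
from .circular import wrap_deg
from .presets import ModelPreset, get_preset
from .simulator import run_trial_pairs
from .task_protocol import TrialPairSpec

__all__ = [
    "BatteryConfig",
    "run_battery",
    "battery_summary",
    "measure_bump_amplitudes",
    "replicate_figure",
    "FIGURE_NAMES",
    "tuning_curve",
]

FIGURE_NAMES = ("fig1", "fig2", "fig3", "fig4", "s1", "s2", "s3")


@dataclass(frozen=True)
class BatteryConfig:
    """One battery: a preset run over an angle x seed grid at fixed timing."""

    preset: str = "model1"
    n_angles: int = 32
    seeds_per_angle: int = 20
    theta1: float = 180.0
    delay1: float = 1.0
    delay2: float = 10.0
    iti: float = 1.0
    decode_times: tuple = (0.0, 1.0, 3.0, 6.0, 10.0)
    settle: float = 0.5
    master_seed: int = 0
    n_boot: int = 10_000
    zero_noise: bool = False
    n_neurons: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.seeds_per_angle < 1:
            raise ValueError("grid sizes must be >= 1")
        get_preset(self.preset)  # raises on unknown name
        object.__setattr__(self, "decode_times", tuple(float(t) for t in self.decode_times))

    def with_(self, **kwargs) -> "BatteryConfig":
        return replace(self, **kwargs)


def _cell_seed(master_seed: int, angle_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(angle_idx), int(rep)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _resolve_preset(config: BatteryConfig) -> ModelPreset:
    preset = get_preset(config.preset)
    net = preset.net
    if config.zero_noise:
        net = net.with_(sigma_n=0.0)
    if config.n_neurons is not None:
        net = net.with_(n_neurons=config.n_neurons)
    return replace(preset, net=net)


def run_battery(
    config: BatteryConfig,
    out_dir: Optional[str] = None,
    force: bool = False,
    max_batch: int = 1024,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all (angle x seed) simulations of a battery and summarize.

    Returns ``(sim_df, summary_df)``: one simulation row per decode time,
    and one summary row per decode time with the DoG fit and bootstrap CI.
    With ``out_dir`` the tables are written as CSV next to a completion
    marker; a completed battery is loaded from disk instead of re-run, and
    partial output from an interrupted run is refused unless ``force``.
    """
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sims_path = out / f"{config.preset}_sims.csv"
        summary_path = out / f"{config.preset}_summary.csv"
        marker = out / f"{config.preset}_done.json"
        if marker.exists() and not force:
            saved = json.loads(marker.read_text())
            if saved == _config_tag(config):
                return pd.read_csv(sims_path), pd.read_csv(summary_path)
            raise FileExistsError(
                f"{marker} belongs to a different configuration; pass force=True"
            )
        if (sims_path.exists() or summary_path.exists()) and not force:
            raise FileExistsError(
                f"partial battery output in {out}; pass force=True to overwrite"
            )

    preset = _resolve_preset(config)
    thetas = np.arange(config.n_angles) * (360.0 / config.n_angles)
    specs, seeds = [], []
    for k, th2 in enumerate(thetas):
        for j in range(config.seeds_per_angle):
            specs.append(
                TrialPairSpec(
                    theta1=config.theta1,
                    theta2=float(th2),
                    delay1=config.delay1,
                    delay2=config.delay2,
                    iti=config.iti,
                    decode_times=config.decode_times,
                    settle=config.settle,
                )
            )
            seeds.append(_cell_seed(config.master_seed, k, j))

    results = []
    for lo in range(0, len(specs), max_batch):
        results.extend(
            run_trial_pairs(
                specs[lo : lo + max_batch],
                preset.net,
                plasticity=preset.plasticity,
                stim=preset.stim,
                reset=preset.reset,
                adapt=preset.adaptation,
                seeds=seeds[lo : lo + max_batch],
            )
        )

    rows = []
    for res in results:
        sp = res.spec
        for tau, decoded in sorted(res.decoded.items()):
            rows.append(
                {
                    "preset": config.preset,
                    "seed": res.seed,
                    "theta1": sp.theta1,
                    "theta2": sp.theta2,
                    "delay": tau,
                    "iti": sp.iti,
                    "decode_time": tau,
                    "decoded_deg": decoded,
                    "error_deg": signed_circular_error(decoded, sp.theta2),
                    "rel_angle_deg": wrap_deg(sp.theta1 - sp.theta2),
                }
            )
    sim_df = pd.DataFrame(rows)
    summary_df = battery_summary(sim_df, config)

    if out_dir is not None:
        sim_df.to_csv(sims_path, index=False)
        summary_df.to_csv(summary_path, index=False)
        marker.write_text(json.dumps(_config_tag(config)))
    return sim_df, summary_df


def _config_tag(config: BatteryConfig) -> dict:
    d = asdict(config)
    d["decode_times"] = list(d["decode_times"])
    return d


def battery_summary(sim_df: pd.DataFrame, config: BatteryConfig) -> pd.DataFrame:
    """Per-decode-time DoG fit + bootstrap CI for a battery's simulations.

    With ``config.n_boot = 0`` the bootstrap is skipped and the CI columns
    are left empty.
    """
    rows = []
    for ti, (tau, grp) in enumerate(sorted(sim_df.groupby("decode_time"))):
        if config.n_boot <= 0:
            fit = fit_dog(grp)
        else:
            fit = bootstrap_peak_to_peak(
                grp,
                n_boot=config.n_boot,
                seed=_cell_seed(config.master_seed, 1_000_000 + ti, 0),
            )
        rows.append(
            {
                "preset": config.preset,
                "delay": tau,
                "iti": config.iti,
                "n": fit.n_rows,
                "amp_a": fit.amp_a,
                "width_w": fit.width_w,
                "peak_to_peak": fit.peak_to_peak,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "n_boot": fit.n_boot,
            }
        )
    return pd.DataFrame(rows)


def tuning_curve(sim_df: pd.DataFrame, decode_time: float) -> pd.DataFrame:
    """Mean signed error per relative angle at one decode time."""
    grp = sim_df[sim_df["decode_time"] == decode_time]
    out = (
        grp.groupby("rel_angle_deg")["error_deg"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_error_deg", "sem": "sem_error_deg", "count": "n"})
    )
    return out


def measure_bump_amplitudes(
    preset_name: str = "model2",
    n_reps: int = 10,
    master_seed: int = 0,
    delay1: float = 1.0,
    iti: float = 1.0,
    window_ms: float = 200.0,
    zero_noise: bool = False,
    iti_at: str = "early",
    n_neurons: Optional[int] = None,
) -> dict:
    """Bump amplitude at mid-delay and in the ITI, and their ratio.

    Amplitude is the peak of the trial-averaged rate profile minus its
    circular baseline (the profile minimum), each profile averaged over a
    ``window_ms`` window.  The delay window is centered at the midpoint of
    the first delay.  The ITI window starts at the end of the response
    period (``iti_at="early"``, the default — the residual after a partial
    reset is transient, so this window characterizes the activity that
    actually leaks into the inter-trial interval) or is centered at the ITI
    midpoint (``iti_at="mid"``).
    """
    if iti_at not in ("early", "mid"):
        raise ValueError("iti_at must be 'early' or 'mid'")
    preset = _resolve_preset(
        BatteryConfig(preset=preset_name, delay1=delay1, iti=iti, zero_noise=zero_noise,
                      decode_times=(), n_neurons=n_neurons)
    )
    cue_ms = preset.stim.duration * 1000.0
    settle_ms = 500.0
    mid_delay = settle_ms + cue_ms + delay1 * 1000.0 / 2.0
    iti_start = settle_ms + cue_ms + delay1 * 1000.0 + preset.reset.reset_duration
    if iti_at == "early":
        iti_window = (iti_start, iti_start + window_ms)
    else:
        mid_iti = iti_start + iti * 1000.0 / 2.0
        iti_window = (mid_iti - window_ms / 2.0, mid_iti + window_ms / 2.0)
    windows = {
        "mid_delay": (mid_delay - window_ms / 2.0, mid_delay + window_ms / 2.0),
        "iti": iti_window,
    }
    specs = [
        TrialPairSpec(
            theta1=180.0, theta2=90.0, delay1=delay1, delay2=0.5, iti=iti,
            decode_times=(), settle=0.5,
        )
        for _ in range(n_reps)
    ]
    seeds = [_cell_seed(master_seed, 0, j) for j in range(n_reps)]
    results = run_trial_pairs(
        specs,
        preset.net,
        plasticity=preset.plasticity,
        stim=preset.stim,
        reset=preset.reset,
        adapt=preset.adaptation,
        seeds=seeds,
        record_profile_windows=windows,
    )
    out = {}
    for label in windows:
        profile = np.mean([r.profiles[label] for r in results], axis=0)
        out[f"amp_{label}"] = float(profile.max() - profile.min())
    out["ratio"] = out["amp_iti"] / out["amp_mid_delay"]
    out["n_reps"] = n_reps
    return out


def _scaled_seeds(scale: str) -> int:
    if scale == "full":
        return 100
    if scale == "reduced":
        return 20
    raise ValueError("scale must be 'full' or 'reduced'")


def replicate_figure(
    name: str,
    scale: str = "reduced",
    master_seed: int = 0,
    out_dir: Optional[str] = None,
    n_boot: int = 10_000,
) -> dict:
    """Run the battery (or batteries) behind a named results figure.

    Returns a dict of plot-ready DataFrames ("sims", "summary", per-ITI
    summaries for the ITI sweeps, "tuning" curves where the figure shows
    them).  Reduced scale uses 20 seeds per angle; full scale the printed
    100.
    """
    if name not in FIGURE_NAMES:
        raise ValueError(
            f"unknown figure {name!r}; valid names: {', '.join(FIGURE_NAMES)}"
        )
    seeds = _scaled_seeds(scale)
    base = BatteryConfig(
        seeds_per_angle=seeds, master_seed=master_seed, n_boot=n_boot
    )
    outputs: dict = {}

    def _run(config: BatteryConfig, tag: str):
        sub = None if out_dir is None else str(Path(out_dir) / tag)
        return run_battery(config, out_dir=sub)

    if name == "fig1":
        sims, summary = _run(base.with_(preset="model1"), "model1")
        outputs = {"sims": sims, "summary": summary}
    elif name == "fig2":
        sims, summary = _run(base.with_(preset="model2"), "model2")
        amps = measure_bump_amplitudes("model2", master_seed=master_seed)
        outputs = {
            "sims": sims,
            "summary": summary,
            "bump_amplitudes": pd.DataFrame([amps]),
            "tuning": tuning_curve(sims, 1.0),
        }
    elif name in ("fig3", "fig4"):
        preset = "model3" if name == "fig3" else "model3_adaptation"
        sims, summary = _run(base.with_(preset=preset), f"{preset}_iti1")
        iti_rows = [summary[summary["delay"] == 10.0]]
        for iti in (3.0, 6.0, 10.0):
            _, s = _run(
                base.with_(preset=preset, iti=iti, decode_times=(10.0,)),
                f"{preset}_iti{iti:g}",
            )
            iti_rows.append(s)
        outputs = {
            "sims": sims,
            "summary": summary,
            "iti_sweep": pd.concat(iti_rows, ignore_index=True),
            "tuning": tuning_curve(sims, 10.0),
        }
    elif name == "s1":
        sims, summary = _run(
            base.with_(preset="model2_noreset", decode_times=(0.0, 10.0)),
            "model2_noreset",
        )
        outputs = {"sims": sims, "summary": summary}
    elif name == "s2":
        out2 = {}
        for preset in ("model3", "model3_narrow"):
            sims, summary = _run(
                base.with_(preset=preset, decode_times=(10.0,)), f"{preset}_s2"
            )
            out2[f"sims_{preset}"] = sims
            out2[f"summary_{preset}"] = summary
            out2[f"tuning_{preset}"] = tuning_curve(sims, 10.0)
        outputs = out2
    elif name == "s3":
        sims, summary = _run(base.with_(preset="model2_adaptation"), "model2_adaptation")
        outputs = {"sims": sims, "summary": summary}

    if out_dir is not None:
        for key, df in outputs.items():
            df.to_csv(Path(out_dir) / f"{name}_{key}.csv", index=False)
    return outputs
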