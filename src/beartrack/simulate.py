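"""Synthetic telemetry studies with the statistical structure the pipeline assumes.

The study's raw telemetry is not publicly deposited, so this module generates
complete stand-in studies: an hourly coastal temperature series, per-bear
movement driven by a two-state Markov chain with logit-linear temperature
effects (gamma step lengths, von Mises turn angles on a 4-h behavioural
grid), duty-cycled Argos/GPS observation with class-structured positional
error and missed fixes, and design-specific tag detachment and battery
failure.  Ground truth (latent states, true positions, generating
parameters, failure times) is returned alongside the emitted fix tables so
every pipeline stage can be tested closed-loop.

Latent truth lives on the 4-h behavioural grid — the scale on which step
means are reported (0.74 km per 4 h for traveling, i.e. ~0.19 km/h); true
positions on the 1-h grid are linear interpolations within steps so that 2-h
GPS duty cycles can be sampled.

The default configuration encodes the study conditions: state-2 step mean
0.74 km, the ear-tag Argos class mix (6/14/14/13/18/36% for 3/2/1/0/A/B,
normalized), 4-h Argos and 2-h GPS duty cycles, ~0.95 dwell probabilities,
and a negative temperature effect on the resting-to-traveling transition
(bears travel more as temperatures cool).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .core import write_deployments, write_fixes, write_temperature
from .geo import LocalProjection
from .hmm import HmmParams, stationary_distribution, transition_matrices
from .regularize import DEFAULT_ARGOS_SD_KM

__all__ = ["SimConfig", "SimTruth", "SimStudy", "simulate_temperature", "simulate_track", "simulate_observation", "simulate_study"]


def _default_hmm_truth() -> HmmParams:
    # resting dwell ~0.95 at 0 deg C with the 2->1 intercept set so the
    # stationary law sits near 70% resting / 30% traveling there;
    # resting->traveling switching increases as temperature falls
    # (negative linear coefficient)
    return HmmParams(
        step_mean=np.array([0.02, 0.74]),
        step_sd=np.array([0.02, 0.5]),
        turn_mean=np.array([np.pi, 0.0]),
        turn_conc=np.array([0.7, 1.5]),
        beta12=np.array([-2.944, -0.06]),
        beta21=np.array([-2.024, 0.04]),
        delta=np.array([0.7, 0.3]),
    )


#: ear-tag Argos location-class mix (3,2,1,0,A,B); the printed percentages
#: (6/14/14/13/18/36) sum to 101 due to rounding, so they are normalized
DEFAULT_CLASS_MIX = tuple(np.array([6.0, 14.0, 14.0, 13.0, 18.0, 36.0]) / 101.0)


@dataclass
class SimConfig:
    """Generator configuration; defaults encode the study conditions."""

    n_bears: int = 10
    n_steps: int = 500  # 4-h behavioural steps per bear
    step_hours: float = 4.0
    start_time: str = "2021-09-01T00:00:00Z"
    designs: tuple = ("seatrkr",) * 6 + ("ear",) * 4
    hmm_truth: HmmParams = field(default_factory=_default_hmm_truth)
    # temperature model: seasonal linear trend + diel sinusoid + AR(1) noise
    temp_start_c: float = 10.0
    temp_cooling_c_per_day: float = -0.25
    temp_diel_amp_c: float = 3.0
    temp_ar_coef: float = 0.9
    temp_ar_sd: float = 0.8
    station_id: str = "synthetic_coastal_station"
    station_lon: float = -94.07
    station_lat: float = 58.74
    # observation model
    duty_cycle_h: dict = field(
        default_factory=lambda: {"pentagon": 4.0, "tribrush": 4.0, "ear": 4.0, "seatrkr": 2.0}
    )
    fix_success: float = 0.9
    class_mix: tuple = DEFAULT_CLASS_MIX
    class_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_SD_KM))
    gps_sd_km: float = 0.02
    heavy_tail: bool = False  # mixture tail on positional error
    # tag failure
    detach_mean_days: dict = field(
        default_factory=lambda: {"pentagon": 22.0, "tribrush": 47.0, "seatrkr": 58.0}
    )
    ear_battery_mean_days: float = 121.0
    ear_battery_sd_days: float = 40.0
    ear_detach_prob: float = 0.07
    fur_battery_days: float = 165.0  # fur tags detach before battery exhaustion
    inactivity_onset_h: float = 12.0  # stillness before the tag flags inactivity
    inactive_transmit_days: float = 2.0
    # geography: latitudes above the boundary are marine (Hudson Bay)
    coast_lat: float = 58.0
    start_lon: float = -93.5
    start_lat: float = 57.8
    seed: int = 0

    @classmethod
    def recovery(cls, n_bears: int = 10, n_steps: int = 500, seed: int = 0) -> "SimConfig":
        """Noise-free preset for parameter-recovery harnesses.

        Clean 4-h GPS-like observation of the latent truth: no positional
        noise, no missed fixes, no tag failure, bears started well inland so
        tracks stay terrestrial.
        """
        return cls(
            n_bears=n_bears,
            n_steps=n_steps,
            designs=("seatrkr",) * n_bears,
            duty_cycle_h={"pentagon": 4.0, "tribrush": 4.0, "ear": 4.0, "seatrkr": 4.0},
            fix_success=1.0,
            gps_sd_km=0.0,
            class_sd_km={k: 0.0 for k in DEFAULT_ARGOS_SD_KM},
            detach_mean_days={"pentagon": 1e9, "tribrush": 1e9, "seatrkr": 1e9},
            ear_battery_mean_days=1e9,
            ear_battery_sd_days=0.0,
            ear_detach_prob=0.0,
            fur_battery_days=1e9,
            start_lat=57.0,
            seed=seed,
        )


@dataclass
class SimTruth:
    """Generating parameters and latent truth of one synthetic study."""

    params: HmmParams
    states: dict  # tag_id -> latent state (1-based) per 4-h step
    steps_km: dict  # tag_id -> true step lengths
    temps: dict  # tag_id -> covariate at step start
    positions_1h: dict  # tag_id -> DataFrame(time, lon, lat, state, on_land)
    failures: dict  # tag_id -> {"cause", "event_h"}

    @property
    def occupancy(self) -> np.ndarray:
        """Overall proportion of generating steps in each state."""
        all_states = np.concatenate([v for v in self.states.values()])
        return np.bincount(all_states - 1, minlength=2) / all_states.size


@dataclass
class SimStudy:
    fixes: pd.DataFrame
    deployments: pd.DataFrame
    temperature: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def write(self, out_dir) -> None:
        """Emit pipeline-readable CSVs plus a truth file and config echo."""
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixes(self.fixes, out / "fixes.csv")
        write_deployments(self.deployments, out / "deployments.csv")
        write_temperature(self.temperature, out / "temperature.csv")
        truth = {
            "occupancy": self.truth.occupancy.tolist(),
            "step_mean": self.truth.params.step_mean.tolist(),
            "step_sd": self.truth.params.step_sd.tolist(),
            "turn_mean": self.truth.params.turn_mean.tolist(),
            "turn_conc": self.truth.params.turn_conc.tolist(),
            "beta12": self.truth.params.beta12.tolist(),
            "beta21": self.truth.params.beta21.tolist(),
            "states": {k: v.tolist() for k, v in self.truth.states.items()},
            "failures": {
                k: {kk: (float(vv) if isinstance(vv, (int, float, np.floating)) else vv) for kk, vv in f.items()}
                for k, f in self.truth.failures.items()
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple, np.ndarray)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        cfg = asdict(self.config)
        cfg["hmm_truth"] = {k: np.asarray(v).tolist() for k, v in asdict(self.config.hmm_truth).items()}
        (out / "config_echo.yaml").write_text(yaml.safe_dump(plain(cfg)))


def clean_step_series(study: SimStudy):
    """Step series straight from a noise-free study's on-grid fixes.

    Intended for the :meth:`SimConfig.recovery` preset, where observed fixes
    coincide with the true 4-h positions: each tag's fixes become one regular
    track, the temperature covariate is attached, and steps/turns are
    derived.  Bypasses filtering/regularization for closed-loop parameter
    recovery.
    """
    from .core import attach_temperature
    from .hmm import build_step_series
    from .regularize import RegularTrack

    tracks = []
    for tag_id, g in study.fixes.groupby("tag_id", sort=False):
        data = attach_temperature(g[["time", "lon", "lat"]].reset_index(drop=True), study.temperature)
        tracks.append(RegularTrack(str(tag_id), 0, study.config.step_hours, data))
    return build_step_series(tracks)


def simulate_temperature(config: SimConfig, duration_h: float, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hourly station series: linear seasonal trend + diel sinusoid + AR(1) noise."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    hours = np.arange(int(np.ceil(duration_h)) + 1, dtype=float)
    trend = config.temp_start_c + config.temp_cooling_c_per_day * hours / 24.0
    diel = config.temp_diel_amp_c * np.sin(2.0 * np.pi * hours / 24.0)
    e = np.zeros(len(hours))
    phi, sd = config.temp_ar_coef, config.temp_ar_sd
    stat_sd = sd / np.sqrt(1.0 - phi**2) if abs(phi) < 1 else sd
    e[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sd, size=len(hours) - 1)
    for k in range(1, len(hours)):
        e[k] = phi * e[k - 1] + innov[k - 1]
    t0 = pd.Timestamp(config.start_time)
    return pd.DataFrame(
        {
            "station_id": config.station_id,
            "station_lon": config.station_lon,
            "station_lat": config.station_lat,
            "time": t0 + pd.to_timedelta(hours, unit="h"),
            "temp_c": trend + diel + e,
        }
    )


def simulate_track(config: SimConfig, temperature: pd.DataFrame, rng: np.random.Generator):
    """One bear's latent-state path and true positions.

    Returns ``(positions_1h, states, steps_km, turns_rad, temps)`` where
    ``positions_1h`` is a DataFrame on the hourly grid (time, lon, lat,
    state, on_land) and the remaining arrays live on the 4-h step grid.
    The latent chain uses the transition matrix at the source step's
    temperature; step vectors accumulate on a local plane anchored at the
    start position and map back through an azimuthal-equidistant projection.
    """
    p = config.hmm_truth
    n = config.n_steps
    t0 = pd.Timestamp(config.start_time)
    step_h = config.step_hours
    station = temperature.sort_values("time")
    temp_hours = (station["time"] - t0).dt.total_seconds().to_numpy() / 3600.0
    temp_vals = station["temp_c"].to_numpy(dtype=float)
    step_times_h = np.arange(n) * step_h
    temps = np.interp(step_times_h, temp_hours, temp_vals)
    if step_times_h[-1] > temp_hours[-1] + 1e-9:
        raise ValueError("temperature series does not cover the track span")

    G = transition_matrices(p, temps)
    states = np.zeros(n, dtype=np.int64)
    states[0] = rng.choice(2, p=stationary_distribution(G[0]))
    for t in range(1, n):
        states[t] = rng.choice(2, p=G[t - 1, states[t - 1]])

    shape = (p.step_mean / p.step_sd) ** 2
    scale = p.step_sd**2 / p.step_mean
    steps = rng.gamma(shape[states], scale[states])
    turns = np.zeros(n)
    turns[1:] = rng.vonmises(p.turn_mean[states[1:]], p.turn_conc[states[1:]])
    heading = np.zeros(n)
    heading[0] = rng.uniform(-np.pi, np.pi)
    heading[1:] = turns[1:]
    heading = np.cumsum(heading)

    x = np.zeros(n + 1)
    y = np.zeros(n + 1)
    x[1:] = np.cumsum(steps * np.sin(heading))
    y[1:] = np.cumsum(steps * np.cos(heading))

    # hourly positions: linear interpolation within each 4-h step
    hours = np.arange(int(n * step_h) + 1, dtype=float)
    vert_h = np.arange(n + 1) * step_h
    hx = np.interp(hours, vert_h, x)
    hy = np.interp(hours, vert_h, y)
    state_1h = states[np.minimum((hours / step_h).astype(int), n - 1)] + 1

    proj = LocalProjection(config.start_lon, config.start_lat)
    lon, lat = proj.inverse(hx, hy)
    positions = pd.DataFrame(
        {
            "time": t0 + pd.to_timedelta(hours, unit="h"),
            "lon": np.atleast_1d(lon),
            "lat": np.atleast_1d(lat),
            "state": state_1h,
            "on_land": np.atleast_1d(lat) <= config.coast_lat,
        }
    )
    return positions, states + 1, steps, turns, temps


def _draw_failure(config: SimConfig, design: str, rng: np.random.Generator) -> tuple[str, float]:
    """(cause, event hour) for one tag; cause 'detached' or 'stopped'."""
    if design == "ear":
        battery_h = max(rng.normal(config.ear_battery_mean_days, config.ear_battery_sd_days), 5.0) * 24.0
        if rng.random() < config.ear_detach_prob:
            detach_h = rng.uniform(0.0, battery_h)
            return "detached", detach_h
        return "stopped", battery_h
    mean_d = config.detach_mean_days.get(design, 50.0)
    detach_h = rng.exponential(mean_d) * 24.0
    battery_h = config.fur_battery_days * 24.0
    if detach_h < battery_h:
        return "detached", detach_h
    return "stopped", battery_h


def simulate_observation(
    positions_1h: pd.DataFrame,
    design: str,
    config: SimConfig,
    rng: np.random.Generator,
    tag_id: str,
    bear_id: str,
) -> tuple[pd.DataFrame, dict]:
    """Observe a true hourly track through one tag's reporting process.

    Thins the truth to the design's duty cycle, drops fixes at
    ``1 - fix_success``, perturbs positions with class-structured isotropic
    error (Argos) or GPS error, and applies detachment/battery failure: once
    the tag has been motionless past the inactivity onset it emits
    inactivity-flagged fixes from the detachment site for a limited window,
    then falls silent.
    """
    duty = float(config.duty_cycle_h[design])
    t0 = positions_1h["time"].iloc[0]
    hours = (positions_1h["time"] - t0).dt.total_seconds().to_numpy() / 3600.0
    cause, event_h = _draw_failure(config, design, rng)
    detach_h = event_h if cause == "detached" else np.inf
    if cause == "stopped":
        end_h = event_h
    else:
        end_h = detach_h + config.inactivity_onset_h + config.inactive_transmit_days * 24.0

    is_gps = design == "seatrkr"
    classes = np.array(["3", "2", "1", "0", "A", "B"])
    mix = np.asarray(config.class_mix, dtype=float)
    mix = mix / mix.sum()

    # true (or frozen, post-detachment) position at each duty-cycle time
    lon_t = positions_1h["lon"].to_numpy()
    lat_t = positions_1h["lat"].to_numpy()
    rows = []
    k = 0
    while True:
        th = k * duty
        k += 1
        if th > hours[-1] or th > end_h:
            break
        h_eff = min(th, detach_h)  # frozen at the detachment site afterwards
        i = int(np.searchsorted(hours, h_eff, side="right")) - 1
        frac = (h_eff - hours[i]) / (hours[i + 1] - hours[i]) if i + 1 < len(hours) else 0.0
        lon0 = lon_t[i] + (lon_t[i + 1] - lon_t[i]) * frac if i + 1 < len(hours) else lon_t[i]
        lat0 = lat_t[i] + (lat_t[i + 1] - lat_t[i]) * frac if i + 1 < len(hours) else lat_t[i]
        inactive = th >= detach_h + config.inactivity_onset_h
        if rng.random() > config.fix_success:
            continue
        if is_gps:
            sd_km = config.gps_sd_km
            loc_class = None
            h_error_m = float(np.clip(rng.lognormal(np.log(10.0), 0.5), 1.0, 200.0))
        else:
            loc_class = classes[rng.choice(6, p=mix)]
            sd_km = float(config.class_sd_km[loc_class])
            h_error_m = None
        if config.heavy_tail and rng.random() < 0.05:
            sd_km *= 4.0
        if sd_km > 0:
            dx, dy = rng.normal(0.0, sd_km, size=2)
        else:
            dx = dy = 0.0
        lat_obs = lat0 + dy / 111.195
        lon_obs = lon0 + dx / (111.195 * np.cos(np.radians(lat0)))
        rows.append(
            {
                "tag_id": tag_id,
                "bear_id": bear_id,
                "time": t0 + pd.Timedelta(hours=th),
                "lon": lon_obs,
                "lat": lat_obs,
                "source": "gps" if is_gps else "argos",
                "loc_class": loc_class,
                "h_error_m": h_error_m,
                "activity": "inactive" if inactive else "active",
                "on_land": bool(lat_obs <= config.coast_lat),
            }
        )
    fixes = pd.DataFrame(rows)
    return fixes, {"cause": cause, "event_h": float(event_h)}


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> SimStudy:
    """Generate a complete synthetic study; deterministic under the seed."""
    config = config if config is not None else SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    duration_h = config.n_steps * config.step_hours + 48.0
    temperature = simulate_temperature(config, duration_h, rng)

    fixes_parts = []
    dep_rows = []
    states = {}
    steps_km = {}
    temps = {}
    positions = {}
    failures = {}
    for b in range(config.n_bears):
        design = config.designs[b % len(config.designs)]
        tag_id = f"tag{b + 1:02d}"
        bear_id = f"bear{b + 1:02d}"
        pos, st, sk, _, tv = simulate_track(config, temperature, rng)
        fx, failure = simulate_observation(pos, design, config, rng, tag_id, bear_id)
        states[tag_id] = st
        steps_km[tag_id] = sk
        temps[tag_id] = tv
        positions[tag_id] = pos
        failures[tag_id] = failure
        if not fx.empty:
            fixes_parts.append(fx)
        attach = pd.Timestamp(config.start_time)
        last = fx["time"].iloc[-1] if not fx.empty else attach
        dep_rows.append(
            {
                "tag_id": tag_id,
                "bear_id": bear_id,
                "design": design,
                "attach_time": attach,
                "season": "spring" if design == "ear" else "fall",
                "adhesive": False,
                "fix_interval_h": float(config.duty_cycle_h[design]),
                "end_time": last,
                "end_cause": failure["cause"],
            }
        )
    fixes = (
        pd.concat(fixes_parts, ignore_index=True)
        .sort_values(["tag_id", "time"], kind="mergesort")
        .reset_index(drop=True)
        if fixes_parts
        else pd.DataFrame()
    )
    deployments = pd.DataFrame(dep_rows)
    truth = SimTruth(config.hmm_truth, states, steps_km, temps, positions, failures)
    return SimStudy(fixes, deployments, temperature, truth, config)
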