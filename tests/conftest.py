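import numpy as np
import pandas as pd
import pytest

from beartrack.hmm import HmmParams, StepSeries
from beartrack.simulate import SimConfig, clean_step_series, simulate_study

T0 = pd.Timestamp("2021-09-01T00:00:00Z")


def make_fixes(
    times_h,
    lons=None,
    lats=None,
    tag_id="tagA",
    source="gps",
    on_land=True,
    activity="active",
    loc_class="1",
):
    """Build a schema-complete fix table from hour offsets."""
    n = len(times_h)
    lons = np.full(n, -93.5) if lons is None else np.asarray(lons, dtype=float)
    lats = np.full(n, 57.5) if lats is None else np.asarray(lats, dtype=float)
    on_land = np.full(n, on_land) if np.isscalar(on_land) else np.asarray(on_land)
    activity = [activity] * n if isinstance(activity, str) else list(activity)
    is_gps = source == "gps"
    return pd.DataFrame(
        {
            "tag_id": tag_id,
            "bear_id": "bear_" + tag_id,
            "time": T0 + pd.to_timedelta(np.asarray(times_h, dtype=float), unit="h"),
            "lon": lons,
            "lat": lats,
            "source": source,
            "loc_class": None if is_gps else loc_class,
            "h_error_m": 10.0 if is_gps else None,
            "activity": activity,
            "on_land": on_land,
        }
    )


def make_series(steps, turns=None, temps=None, segment_id="s0"):
    """StepSeries from raw arrays (first turn NaN unless given)."""
    steps = np.asarray(steps, dtype=float)
    n = len(steps)
    if turns is None:
        turns = np.full(n, np.nan)
        turns[1:] = 0.0
    if temps is None:
        temps = np.zeros(n)
    return StepSeries(
        pd.DataFrame(
            {
                "segment_id": segment_id,
                "step_km": steps,
                "turn_rad": np.asarray(turns, dtype=float),
                "temp_c": np.asarray(temps, dtype=float),
            }
        )
    )


def random_params(rng, p=0, separated=False):
    """Random but well-posed two-state parameters for oracle comparisons."""
    if separated:
        means = np.array([0.02, 1.0])
    else:
        means = np.sort(rng.uniform(0.05, 1.5, 2))
    k = 1 + p
    return HmmParams(
        step_mean=means,
        step_sd=rng.uniform(0.3, 1.2, 2) * means,
        turn_mean=rng.uniform(-np.pi, np.pi, 2),
        turn_conc=rng.uniform(0.1, 3.0, 2),
        beta12=np.concatenate([[rng.uniform(-3, -0.5)], rng.normal(0, 0.3, k - 1)]),
        beta21=np.concatenate([[rng.uniform(-3, -0.5)], rng.normal(0, 0.3, k - 1)]),
        delta=np.array([0.6, 0.4]),
    )


def random_series(rng, T, n_segments=1, with_temp=True):
    frames = []
    for s in range(n_segments):
        steps = rng.gamma(2.0, 0.3, T) + 1e-4
        turns = np.full(T, np.nan)
        turns[1:] = rng.uniform(-np.pi, np.pi, T - 1)
        temps = rng.normal(0.0, 5.0, T) if with_temp else np.zeros(T)
        frames.append(
            pd.DataFrame(
                {"segment_id": f"seg{s}", "step_km": steps, "turn_rad": turns, "temp_c": temps}
            )
        )
    return StepSeries(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def clean_study():
    """Small noise-free synthetic study used for closed-loop HMM checks."""
    return simulate_study(SimConfig.recovery(n_bears=6, n_steps=300, seed=11))


@pytest.fixture(scope="session")
def clean_series(clean_study):
    return clean_step_series(clean_study)
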