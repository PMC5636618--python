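"""Synthetic per-animal datasets with the statistical structure the analyses assume.

The generator stands in for the animal study: it emits per-animal
biodistribution tables (%ID/g at 2/4/24/48/72 h, cross-sectional animals per
time point as in a terminal-excision design), longitudinal tumour-volume
trajectories with derived time-to-endpoint records, and DCE signal series at
three imaging sessions.  Group-level means/SDs and qualitative behaviour
(regression depth, regrowth timing, fraction of complete regressions) are
calibrated to the published group summaries; see docs/methods.md for what the
generator deliberately does and does not emulate.

All generators are pure functions of (config, seed); per-generator substreams
are derived deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SynthConfig", "gen_biodistribution", "gen_growth_cohort", "gen_dce"]

IMAGING_DAYS = (0.0, 6.0, 7.0, 13.0, 17.0, 20.0, 27.0, 34.0, 41.0, 48.0, 53.0)

GROUPS = ("control", "ebrt", "mrt", "ebrt_mrt", "mrt_ebrt")


def _default_biodistribution() -> dict:
    return {
        "times_h": [2.0, 4.0, 24.0, 48.0, 72.0],
        "n_per_time": [3, 3, 3, 3, 2],
        "groups": {
            "mrt": {
                "means": [10.89, 10.94, 3.57, 1.36, 0.80],
                "sds": [4.06, 1.80, 1.57, 0.36, 0.15],
            },
            "ebrt_mrt": {
                "means": [13.50, 13.43, 10.47, 6.73, 5.43],
                "sds": [1.94, 2.37, 1.86, 0.43, 0.69],
            },
        },
        "injected_activity_mbq": 20.0,
    }


def _default_growth() -> dict:
    # surviving_fraction is the mean multiplicative volume remnant once the
    # treatment effect is fully expressed; regrowth resumes exponentially
    # after a per-animal delay. cure_prob = probability of complete
    # regression (no regrowth; censored at the end of observation).
    return {
        "baseline_volume_mm3": 500.0,
        "baseline_sigma": 0.05,
        "measurement_sigma": 0.05,
        "groups": {
            "control": {
                "n": 3,
                "drift_per_day": 0.0,
                "surviving_fraction": 1.0,
                "sf_dispersion": 0.0,
                "kill_start_day": 0.0,
                "kill_ramp_days": 0.0,
                "regrowth_delay_mean_days": 0.0,
                "regrowth_delay_sd_days": 0.0,
                "growth_rate_per_day": 0.095,
                "cure_prob": 0.0,
            },
            "ebrt": {
                "n": 5,
                "drift_per_day": 0.0,
                "surviving_fraction": 0.35,
                "sf_dispersion": 0.40,
                "kill_start_day": 0.0,
                "kill_ramp_days": 6.0,
                "regrowth_delay_mean_days": 8.0,
                "regrowth_delay_sd_days": 1.5,
                "growth_rate_per_day": 0.095,
                "cure_prob": 0.0,
            },
            "mrt": {
                "n": 6,
                "drift_per_day": 0.0115,
                "surviving_fraction": 1.0,
                "sf_dispersion": 0.0,
                "kill_start_day": 0.0,
                "kill_ramp_days": 0.0,
                "regrowth_delay_mean_days": 6.0,
                "regrowth_delay_sd_days": 1.0,
                "growth_rate_per_day": 0.095,
                "cure_prob": 0.0,
            },
            "ebrt_mrt": {
                "n": 5,
                "drift_per_day": 0.0,
                "surviving_fraction": 0.0896,
                "sf_dispersion": 0.30,
                "kill_start_day": 0.0,
                "kill_ramp_days": 6.0,
                "regrowth_delay_mean_days": 10.0,
                "regrowth_delay_sd_days": 2.0,
                "growth_rate_per_day": 0.095,
                "cure_prob": 0.20,
            },
            "mrt_ebrt": {
                "n": 6,
                "drift_per_day": -0.0036,
                "surviving_fraction": 0.30,
                "sf_dispersion": 0.35,
                "kill_start_day": 6.0,
                "kill_ramp_days": 6.0,
                "regrowth_delay_mean_days": 17.0,
                "regrowth_delay_sd_days": 2.0,
                "growth_rate_per_day": 0.095,
                "cure_prob": 0.3333333333,
            },
        },
    }


def _default_dce() -> dict:
    return {
        "n_animals": 3,
        "n_frames": 60,
        "frame_interval_s": 9.0,
        "injection_index": 12,
        "sessions": ["baseline", "24h", "72h"],
        "regions": {
            "tumour": {"baseline_signal": 100.0, "amplitude": 0.5,
                       "multipliers": [1.0, 2.0, 1.8], "session_jitter_sigma": 0.06},
            "muscle": {"baseline_signal": 80.0, "amplitude": 0.35,
                       "multipliers": [1.0, 1.0, 1.0], "session_jitter_sigma": 0.0},
        },
        "animal_amplitude_sigma": 0.15,
        "noise_sigma": 1.0,
        "bolus_alpha": 2.0,
        "bolus_peak_s": 60.0,
    }


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study conditions being emulated."""

    biodistribution: dict = field(default_factory=_default_biodistribution)
    growth: dict = field(default_factory=_default_growth)
    dce: dict = field(default_factory=_default_dce)
    endpoint_volume_mm3: float = 800.0
    censor_day: float = 53.0
    imaging_days: tuple = IMAGING_DAYS

    def __post_init__(self) -> None:
        if self.endpoint_volume_mm3 <= self.growth["baseline_volume_mm3"]:
            raise ValueError("endpoint volume must exceed the baseline volume")
        for g in self.growth["groups"].values():
            if g["n"] < 1:
                raise ValueError("group sizes must be >= 1")
        for spec in self.biodistribution["groups"].values():
            if any(sd < 0 for sd in spec["sds"]):
                raise ValueError("SDs must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["imaging_days"] = tuple(data.get("imaging_days", IMAGING_DAYS))
        return cls(**data)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _truncated_normal(mean, sd, size, rng) -> np.ndarray:
    """Normal(mean, sd) truncated at zero by resampling."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        neg = out < 0
        if not np.any(neg):
            return out
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    return np.clip(out, 0.0, None)


def gen_biodistribution(config: SynthConfig, seed: int) -> pd.DataFrame:
    """Per-animal %ID/g table (columns group, animal_id, time_h, pct_id_per_g).

    Animals are cross-sectional per time point (terminal sampling): values at
    different times are independent draws from the per-timepoint group
    Normal(mean, SD) truncated at zero.
    """
    rng = _rng(seed, 1)
    bio = config.biodistribution
    rows = []
    for group in sorted(bio["groups"]):
        spec = bio["groups"][group]
        for t, mean, sd, n in zip(
            bio["times_h"], spec["means"], spec["sds"], bio["n_per_time"]
        ):
            vals = (
                np.full(n, float(mean))
                if sd == 0
                else _truncated_normal(float(mean), float(sd), n, rng)
            )
            for j, v in enumerate(vals):
                rows.append(
                    {
                        "group": group,
                        "animal_id": f"{group}_t{t:g}_{j}",
                        "time_h": float(t),
                        "pct_id_per_g": float(v),
                    }
                )
    return pd.DataFrame(rows)


def _deterministic_volume(t, v0, drift, drift_end, s_i, kill_start, ramp, delay, g, cured):
    """Noise-free volume at time t for one animal's response profile."""
    logv = np.log(v0) + drift * min(t, drift_end)
    if s_i < 1.0:
        if t <= kill_start:
            kill = 1.0
        elif t >= kill_start + ramp and ramp >= 0:
            kill = s_i
        else:
            kill = 1.0 + (s_i - 1.0) * (t - kill_start) / ramp
        logv += np.log(max(kill, 1e-12))
    if cured:
        # complete regression: continued shrinkage, no regrowth
        t_end = kill_start + ramp
        if t > t_end:
            logv += -0.10 * (t - t_end)
    else:
        if t > delay:
            logv += g * (t - delay)
    return float(np.exp(logv))


def gen_growth_cohort(
    config: SynthConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tumour-volume trajectories and derive time-to-endpoint records.

    Returns (volumes, survival): volumes has columns group, animal_id, day,
    volume_mm3 (rows stop at the endpoint day); survival has columns group,
    animal_id, time_days, event (1 = reached the endpoint volume, 0 = censored
    at the end of observation).
    """
    rng = _rng(seed, 2)
    gp = config.growth
    endpoint = config.endpoint_volume_mm3
    censor = config.censor_day
    days = [d for d in config.imaging_days if d <= censor]
    vol_rows, surv_rows = [], []
    for group in GROUPS:
        if group not in gp["groups"]:
            continue
        prm = gp["groups"][group]
        for i in range(int(prm["n"])):
            aid = f"{group}_{i}"
            v0 = gp["baseline_volume_mm3"] * np.exp(
                rng.normal(0.0, gp["baseline_sigma"]) - gp["baseline_sigma"] ** 2 / 2
            )
            sf = prm["surviving_fraction"]
            disp = prm["sf_dispersion"]
            s_i = min(sf * np.exp(rng.normal(0.0, disp) - disp**2 / 2), 1.0) if sf < 1.0 else 1.0
            delay = max(
                rng.normal(prm["regrowth_delay_mean_days"], prm["regrowth_delay_sd_days"]),
                0.0,
            )
            cured = rng.random() < prm["cure_prob"]
            drift_end = prm["kill_start_day"] if sf < 1.0 else delay
            event_day = None
            for day in days:
                v_det = _deterministic_volume(
                    day,
                    v0,
                    prm["drift_per_day"],
                    drift_end,
                    s_i,
                    prm["kill_start_day"],
                    prm["kill_ramp_days"],
                    delay,
                    prm["growth_rate_per_day"],
                    cured,
                )
                sig = gp["measurement_sigma"]
                v_meas = v_det * np.exp(rng.normal(0.0, sig) - sig**2 / 2)
                vol_rows.append(
                    {"group": group, "animal_id": aid, "day": day, "volume_mm3": v_meas}
                )
                if day > 0 and v_meas >= endpoint:
                    event_day = day
                    break
            if event_day is not None:
                surv_rows.append(
                    {"group": group, "animal_id": aid, "time_days": event_day, "event": 1}
                )
            else:
                surv_rows.append(
                    {"group": group, "animal_id": aid, "time_days": censor, "event": 0}
                )
    return pd.DataFrame(vol_rows), pd.DataFrame(surv_rows)


def _gamma_variate(tau: np.ndarray, alpha: float, t_peak: float) -> np.ndarray:
    """Unit-peak gamma-variate bolus shape, zero before arrival."""
    x = np.clip(tau / t_peak, 0.0, None)
    return np.where(tau > 0, x**alpha * np.exp(alpha * (1.0 - x)), 0.0)


def gen_dce(config: SynthConfig, seed: int) -> pd.DataFrame:
    """DCE signal series per animal/session/region.

    signal = baseline * (1 + amplitude * multiplier * bolus(t - t_inj)) +
    Gaussian noise; the tumour multiplier is elevated at 24 h (and partially
    at 72 h) after irradiation, the muscle multiplier is fixed at 1 across
    sessions.  Columns: animal_id, region, session, time_s, signal.
    """
    rng = _rng(seed, 3)
    dc = config.dce
    times = np.arange(dc["n_frames"]) * dc["frame_interval_s"]
    t_inj = times[dc["injection_index"]]
    rows = []
    for a in range(int(dc["n_animals"])):
        aid = f"mouse_{a}"
        amp_jit = np.exp(
            rng.normal(0.0, dc["animal_amplitude_sigma"])
            - dc["animal_amplitude_sigma"] ** 2 / 2
        )
        for region in sorted(dc["regions"]):
            rspec = dc["regions"][region]
            for si, session in enumerate(dc["sessions"]):
                js = rspec["session_jitter_sigma"]
                mult = rspec["multipliers"][si] * (
                    np.exp(rng.normal(0.0, js) - js**2 / 2) if js > 0 else 1.0
                )
                bolus = _gamma_variate(times - t_inj, dc["bolus_alpha"], dc["bolus_peak_s"])
                clean = rspec["baseline_signal"] * (
                    1.0 + rspec["amplitude"] * amp_jit * mult * bolus
                )
                sig = clean + rng.normal(0.0, dc["noise_sigma"], len(times))
                sig = np.clip(sig, 0.0, None)
                for t, s in zip(times, sig):
                    rows.append(
                        {
                            "animal_id": aid,
                            "region": region,
                            "session": session,
                            "time_s": float(t),
                            "signal": float(s),
                        }
                    )
    return pd.DataFrame(rows)


def write_dataset(config: SynthConfig, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Emit tac.csv, volumes.csv, survival.csv and dce.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tac = gen_biodistribution(config, seed)
    volumes, surv = gen_growth_cohort(config, seed)
    dce = gen_dce(config, seed)
    paths["tac"] = out / "tac.csv"
    tac.to_csv(paths["tac"], index=False)
    paths["volumes"] = out / "volumes.csv"
    volumes.to_csv(paths["volumes"], index=False)
    paths["survival"] = out / "survival.csv"
    surv.to_csv(paths["survival"], index=False)
    paths["dce"] = out / "dce.csv"
    with open(paths["dce"], "w") as fh:
        fh.write(f"# injection_index: {config.dce['injection_index']}\n")
        dce.to_csv(fh, index=False)
    return paths
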