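"""Behavioural summaries of simulated foraging: inhibition of return,
fixation frequencies, precision/volatility sweeps, and firing-rate rasters.

Inhibition of return is quantified as the number of saccades between
successive fixations of the same location; its dependence on the believed
transition precision ω reproduces the qualitative relationship between
volatility and return latency (volatile stimuli regain salience quickly, so
they are re-fixated sooner). Fixation frequency captures the streetlight
effect: locations with low believed sensory precision attract fewer
fixations because observing them resolves little uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import CROSS, Environment, SceneConfig, TrialRecord, build_scene_model, run_trial

__all__ = [
    "IoRSummary",
    "FiringRateRaster",
    "inhibition_of_return",
    "fixation_frequency",
    "volatility_sweep",
    "precision_sweep",
    "firing_rate_raster",
    "ior_sweep_scene",
]


def ior_sweep_scene() -> SceneConfig:
    """Default scene for the volatility / inhibition-of-return sweep.

    Equal sensory precision everywhere with a noisier what-channel
    (``p_correct`` 0.8, ζ = 1) and moderately persistent identities
    (stay probability 0.75): single observations then resolve a stimulus
    only partially, so salience varies gradually with belief sharpness and
    the return latency tracks the believed volatility across the whole ω
    grid rather than saturating at very volatile settings.
    """
    return SceneConfig(
        zeta_by_location=[1.0, 1.0, 1.0, 1.0, 1.0],
        stay_probability=0.75,
        p_correct=0.8,
    )


@dataclass
class IoRSummary:
    """Per-location return-interval statistics.

    ``mean_interval[loc]`` is the mean number of saccades between successive
    fixations of ``loc`` (``nan`` and flagged in ``undefined`` when the
    location was fixated fewer than twice); ``n_returns[loc]`` counts the
    returns; ``intervals[loc]`` keeps the raw interval list.
    """

    mean_interval: dict[int, float]
    n_returns: dict[int, int]
    intervals: dict[int, list[int]] = field(default_factory=dict)

    @property
    def undefined(self) -> list[int]:
        return [loc for loc, m in self.mean_interval.items() if np.isnan(m)]

    def to_frame(self) -> pd.DataFrame:
        locs = sorted(self.mean_interval)
        return pd.DataFrame(
            {
                "location": locs,
                "mean_interval": [self.mean_interval[l] for l in locs],
                "n_returns": [self.n_returns[l] for l in locs],
            }
        )


def _trace(trace) -> list[int]:
    if isinstance(trace, TrialRecord):
        return trace.saccade_trace
    return [int(x) for x in trace]


def inhibition_of_return(trace, locations: list[int] | None = None) -> IoRSummary:
    """Return-interval statistics of a saccade trace.

    The return interval of a location is the index difference between
    successive fixations of that location (consecutive repeats count as
    interval 1). Locations never revisited are flagged undefined.
    """
    seq = _trace(trace)
    if not seq:
        raise ValueError("empty saccade trace")
    locs = sorted(set(seq)) if locations is None else list(locations)
    mean_interval: dict[int, float] = {}
    n_returns: dict[int, int] = {}
    intervals: dict[int, list[int]] = {}
    for loc in locs:
        idx = [i for i, x in enumerate(seq) if x == loc]
        gaps = [b - a for a, b in zip(idx[:-1], idx[1:])]
        intervals[loc] = gaps
        n_returns[loc] = len(gaps)
        mean_interval[loc] = float(np.mean(gaps)) if gaps else float("nan")
    return IoRSummary(mean_interval, n_returns, intervals)


def fixation_frequency(trace, n_locations: int | None = None) -> np.ndarray:
    """Per-location visit fraction of a saccade trace (sums to 1)."""
    seq = _trace(trace)
    if not seq:
        raise ValueError("empty saccade trace")
    n = (max(seq) + 1) if n_locations is None else n_locations
    counts = np.bincount(np.asarray(seq, dtype=int), minlength=n).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _seeded_trials(config: SceneConfig, n_seeds: int, trial_length: int, base_seed: int):
    model = build_scene_model(config)
    for ss in np.random.SeedSequence(base_seed).spawn(n_seeds):
        env = Environment.from_config(config, np.random.default_rng(ss))
        trial_seed = int(ss.generate_state(1)[0] % (2**31))
        yield run_trial(model, env, trial_length, trial_seed, config=config, record_beliefs=False)


def volatility_sweep(
    omega_grid,
    n_seeds: int = 100,
    trial_length: int = 50,
    target_stimulus: int = 0,
    base_config: SceneConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Inhibition of return of one location as a function of believed ω.

    For each ω in the grid, the target stimulus's believed (and true)
    transition precision is set to ω while the other stimuli are believed
    stable (zero volatility); seeded trials are run and the mean return
    interval of the target location aggregated. Returns one row per ω with
    mean, median and sd of the per-seed mean interval.
    """
    omega_grid = [float(w) for w in omega_grid]
    if any(w <= 0 for w in omega_grid):
        raise ValueError("omega grid must be positive")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rows = []
    for i, w in enumerate(omega_grid):
        cfg = base_config if base_config is not None else ior_sweep_scene()
        omega = [np.inf] * cfg.n_stimuli
        omega[target_stimulus] = w
        cfg = SceneConfig(**{**cfg.to_dict(), "omega_by_stimulus": omega,
                             "true_omega_by_stimulus": None})
        target_loc = target_stimulus + 1
        per_seed = []
        for rec in _seeded_trials(cfg, n_seeds, trial_length, base_seed + 7919 * i):
            summ = inhibition_of_return(rec, locations=[target_loc])
            m = summ.mean_interval[target_loc]
            if not np.isnan(m):
                per_seed.append(m)
        rows.append(
            {
                "omega": w,
                "mean_interval": float(np.mean(per_seed)) if per_seed else float("nan"),
                "median_interval": float(np.median(per_seed)) if per_seed else float("nan"),
                "sd_interval": float(np.std(per_seed, ddof=1)) if len(per_seed) > 1 else float("nan"),
                "n_seeds_defined": len(per_seed),
            }
        )
    return pd.DataFrame(rows)


def precision_sweep(
    zeta_low_grid,
    n_seeds: int = 100,
    trial_length: int = 19,
    target_stimulus: int = 0,
    base_config: SceneConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Fixation share of a low-precision location across a grid of believed ζ.

    The target location's believed (and true) sensory precision is set to each
    grid value while the other locations keep the base configuration; the
    fixation share of the target location is aggregated over seeds.
    """
    zeta_low_grid = [float(z) for z in zeta_low_grid]
    if any(z <= 0 for z in zeta_low_grid):
        raise ValueError("zeta grid must be positive")
    rows = []
    target_loc = target_stimulus + 1
    for i, z in enumerate(zeta_low_grid):
        cfg = base_config if base_config is not None else SceneConfig()
        zeta = list(cfg.zeta_by_location)
        zeta[target_loc] = z
        cfg = SceneConfig(**{**cfg.to_dict(), "zeta_by_location": zeta,
                             "true_zeta_by_location": None})
        shares = []
        for rec in _seeded_trials(cfg, n_seeds, trial_length, base_seed + 104729 * i):
            freq = fixation_frequency(rec, n_locations=cfg.n_locations)
            stim_mass = freq[1:].sum()
            shares.append(freq[target_loc] / stim_mass if stim_mass > 0 else float("nan"))
        rows.append(
            {
                "zeta": z,
                "mean_share": float(np.nanmean(shares)),
                "sd_share": float(np.nanstd(shares, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster
# ---------------------------------------------------------------------------


@dataclass
class FiringRateRaster:
    """Posterior expectations of one hidden factor's levels over time.

    ``rates`` is a (time x unit) matrix — each unit encodes one hypothesis
    about the factor's level, its "firing rate" the posterior expectation.
    ``fixation_windows`` marks the time steps during which the location
    reporting on this factor was foveated.
    """

    rates: np.ndarray
    fixation_windows: np.ndarray
    factor: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, columns=[f"unit_{u}" for u in range(self.rates.shape[1])])
        df.insert(0, "t", np.arange(len(df)))
        df["foveated"] = self.fixation_windows.astype(int)
        return df


def firing_rate_raster(trial: TrialRecord, factor: int) -> FiringRateRaster:
    """Simulated neuronal encoding of one stimulus-identity factor.

    Rows are time steps, columns the posterior expectation of each identity
    hypothesis (rows sum to 1); the fixation window marks steps at which the
    stimulus's location was foveated. Between fixations of a volatile
    stimulus the winning unit's expectation decays geometrically toward the
    uniform rate, at the rate set by the ω-modulated transition.
    """
    if not trial.beliefs or factor >= len(trial.beliefs[0]):
        raise ValueError(f"trial does not record beliefs for factor {factor}")
    rates = np.stack([b[factor] for b in trial.beliefs])
    loc = factor + 1  # stimulus f sits at location f+1
    windows = np.array([eye == loc for eye in trial.eye_positions])
    return FiringRateRaster(rates=rates, fixation_windows=windows, factor=factor)
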