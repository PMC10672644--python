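"""Synthetic observation series and ensemble fixtures.

Longitudinal densitometry studies of the menopausal transition report
relative BMD (normalized to the premenopausal value) with a plateau before
perimenopause, an accelerated decline across the transition and a slower
sustained postmenopausal decrease.  The generator emulates such series by
running the forward model under a known ("true") menopause schedule,
sampling the femur-averaged BMD̄ at a follow-up cadence (default every
0.5 years, mimicking annual-to-biennial densitometry), adding i.i.d.
Gaussian measurement noise, and re-normalizing so the first observation is
exactly 1 — closing the generate → calibrate loop needed for parameter
recovery studies without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibrate import ObservationSeries
from .engine import SimulationConfig, SiteSpec, run_simulation
from .menopause import MenopauseSchedule, PRESETS
from .stimulus import LoadSchedule

__all__ = [
    "SyntheticObsConfig",
    "generate_observations",
    "generate_ensemble_fixture",
]


def _default_times() -> np.ndarray:
    return np.arange(-4.0, 15.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class SyntheticObsConfig:
    """Truth schedule, sampling times (years), noise level and seed."""

    schedule: MenopauseSchedule = PRESETS["combined"]
    times: np.ndarray = field(default_factory=_default_times)
    noise_sd: float = 0.005
    seed: int = 0
    load_schedule: LoadSchedule = LoadSchedule()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-d array")
        object.__setattr__(self, "times", t)


def generate_observations(
    cfg: SyntheticObsConfig, base_config: SimulationConfig | None = None
) -> tuple[ObservationSeries, MenopauseSchedule]:
    """Sample noisy relative-BMD̄ observations from a known truth schedule.

    Returns the observation series and the generating schedule (the truth)
    for recovery tests.  With ``noise_sd = 0`` the observations equal the
    forward-model samples exactly.
    """
    base_config = base_config if base_config is not None else SimulationConfig()
    config = replace(
        base_config,
        menopause=cfg.schedule,
        load_schedule=cfg.load_schedule,
        t_start=min(base_config.t_start, float(cfg.times[0])),
        t_end=max(base_config.t_end, float(cfg.times[-1])),
    )
    sim = run_simulation(config)
    clean = np.interp(cfg.times, sim.t_years, sim.bmd_norm)
    rng = np.random.default_rng(cfg.seed)
    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)
    noisy = np.clip(noisy, 1e-6, None) / noisy[0]
    return ObservationSeries(cfg.times.copy(), noisy, cfg.noise_sd or None), cfg.schedule


def generate_ensemble_fixture(
    n_sites: int, vb_range: tuple[float, float] = (0.2, 0.95), seed: int = 0
) -> tuple[SiteSpec, ...]:
    """Deterministic seeded site ensemble spanning a volume-fraction range.

    Sites get strictly increasing v_b values across ``vb_range`` (evenly
    spaced with a small seeded jitter) and normalized positive weights.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = vb_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("vb_range must satisfy 0 < lo < hi < 1")
    rng = np.random.default_rng(seed)
    if n_sites == 1:
        vb = np.array([(lo + hi) / 2.0])
    else:
        vb = np.linspace(lo, hi, n_sites)
        gap = (hi - lo) / (n_sites - 1)
        vb[1:-1] += rng.uniform(-0.2 * gap, 0.2 * gap, size=n_sites - 2)
    weights = rng.uniform(0.5, 1.5, size=n_sites)
    weights /= weights.sum()
    return tuple(
        SiteSpec(f"site_{i}", float(w), float(v))
        for i, (w, v) in enumerate(zip(weights, vb))
    )
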