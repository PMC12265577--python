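"""Reset/step environment interface over the network and surrogate backends.

Both environments share one contract:

    obs_window          = env.reset()
    obs_window, reward, raster, info = env.step(action)   # action in {0, 1}

``action = 1`` injects one DBS pulse into every STN neuron at the start of
the 2 ms control step.  The observation is the FIFO window of recent
beta-power values; the reward is the signed quadratic of its mean.  A step
past the episode end raises ``EpisodeComplete``; ``reset`` begins the next
episode.  Network dynamical state and the biomarker window deliberately
persist across episodes — 60 ms episodes are far shorter than a beta cycle,
so each episode continues the same ongoing recording.

``reseed(seed)`` swaps the background-noise streams without touching the
dynamical state (the disease-progression robustness protocol).
"""

from __future__ import annotations

import numpy as np

from ..biomarker import BiomarkerConfig, ObservationWindow, raster_beta_power
from ..config import EnvConfig
from ..raster import SpikeRaster
from ..reward import compute_reward
from .network import build_network, integrate
from .params import load_params
from .surrogate import SurrogateModel, SurrogateParams

__all__ = ["EpisodeComplete", "BGNetworkEnv", "SurrogateEnv"]


class EpisodeComplete(RuntimeError):
    """step() called after the last control step of the episode."""


class _BaseEnv:
    def __init__(self, config: EnvConfig):
        self.config = config
        self.window = ObservationWindow(n_obs=config.n_obs)
        self._step_idx: int | None = None  # None = needs reset
        self.pulses_delivered = 0

    # subclasses implement _first_reset() and _advance(pulse) -> (p_beta, raster)

    def reset(self) -> ObservationWindow:
        if self._step_idx is None:
            self._first_reset()
        self._step_idx = 0
        return self.window.copy()

    def step(self, action: int):
        if self._step_idx is None:
            raise RuntimeError("call reset() before step()")
        if self._step_idx >= self.config.steps_per_episode:
            raise EpisodeComplete(
                f"episode finished after {self.config.steps_per_episode} steps"
            )
        if action not in (0, 1):
            raise ValueError(f"action must be 0 or 1, got {action!r}")
        p_beta, raster = self._advance(bool(action))
        if action:
            self.pulses_delivered += 1
        if p_beta is not None:
            self.window.push(p_beta)
        reward = compute_reward(self.window.mean, self.config.reward)
        self._step_idx += 1
        info = {
            "terminated": self._step_idx >= self.config.steps_per_episode,
            "p_beta": p_beta,
            "mean_beta": self.window.mean,
            "step": self._step_idx,
            "pulse": bool(action),
            "partial_window": not self.window.filled,
        }
        return self.window.copy(), reward, raster, info

    def reseed(self, seed: int) -> None:
        raise NotImplementedError


class BGNetworkEnv(_BaseEnv):
    """The spiking cortex-basal-ganglia-thalamus backend.

    On first reset the network is built from the config seed and settled for
    ``config.burn_in`` ms; a persistent rolling raster of GPi activity
    (``config.raster_window`` ms) feeds the Welch beta-power estimator after
    every control step.  With burn-in disabled the observation window starts
    unfilled and fills as enough raster accumulates.
    """

    def __init__(self, config: EnvConfig,
                 biomarker: BiomarkerConfig | None = None):
        super().__init__(config)
        if biomarker is None:
            params = load_params(config.condition, config.param_file)
            biomarker = BiomarkerConfig(normalization=params.normalization)
        self.biomarker = biomarker
        self.state = None
        self._rolling: SpikeRaster | None = None

    # -- internals ---------------------------------------------------------
    def _gpi_raster(self, raster: SpikeRaster) -> SpikeRaster:
        idx = self.state.neuron_slice("GPi")
        return SpikeRaster([raster.spikes[i] for i in idx], raster.t0, raster.t1)

    def _beta_now(self, rolling: SpikeRaster) -> float | None:
        if rolling.duration + 1e-9 < self.biomarker.segment:
            return None  # not enough signal to resolve the band yet
        return raster_beta_power(rolling, self.biomarker)

    def _first_reset(self) -> None:
        cfg = self.config
        self.state = build_network(cfg)
        if cfg.burn_in > 0:
            raster = integrate(self.state, cfg.burn_in)
            gpi = self._gpi_raster(raster).tail(cfg.raster_window)
            self._rolling = gpi
            # fill the window with beta estimates at staggered end times,
            # emulating the per-step estimates of the preceding control steps
            for k in range(cfg.n_obs - 1, -1, -1):
                t_end = gpi.t1 - k * cfg.control_step
                sub = gpi.between(max(gpi.t0, t_end - cfg.raster_window), t_end)
                p = self._beta_now(sub)
                if p is not None:
                    self.window.push(p)
        else:
            n_gpi = self.config.population_size
            self._rolling = SpikeRaster([np.empty(0)] * n_gpi, 0.0, 0.0)

    def _advance(self, pulse: bool):
        cfg = self.config
        pulse_times = np.array([0.0]) if pulse else None
        raster = integrate(self.state, cfg.control_step, pulse_times=pulse_times)
        gpi = self._gpi_raster(raster)
        if self._rolling.duration == 0:
            self._rolling = gpi
        else:
            self._rolling = self._rolling.concat(gpi).tail(cfg.raster_window)
        return self._beta_now(self._rolling), raster

    def reseed(self, seed: int) -> None:
        """Swap background-noise streams; dynamics and weights untouched."""
        if self.state is None:
            self._first_reset()
        self.state.reseed_noise(seed)


class SurrogateEnv(_BaseEnv):
    """Beta-oscillator backend with the identical step contract.

    Emits empty rasters (it has no spiking substrate); observation and
    reward semantics match the network backend.
    """

    def __init__(self, config: EnvConfig,
                 params: SurrogateParams | None = None):
        super().__init__(config)
        self.params = params if params is not None else SurrogateParams()
        self.model: SurrogateModel | None = None
        self._t = 0.0

    def _first_reset(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.model = SurrogateModel(self.params, cfg.condition, rng)
        burn_steps = int(round(cfg.burn_in / cfg.control_step))
        for _ in range(burn_steps):
            p = self.model.step(pulse=False)
            self.window.push(p)
            self._t += cfg.control_step

    def _advance(self, pulse: bool):
        p = self.model.step(pulse)
        t0 = self._t
        self._t += self.config.control_step
        raster = SpikeRaster(
            [np.empty(0)] * self.config.population_size, t0, self._t
        )
        return p, raster

    def reseed(self, seed: int) -> None:
        if self.model is None:
            self._first_reset()
        self.model.rng = np.random.default_rng(seed)
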