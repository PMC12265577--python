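"""seadbs: sample-efficient actor-critic control of closed-loop deep brain
stimulation, evaluated in a spiking basal-ganglia environment.

The package couples a conductance-based cortex-basal-ganglia-thalamus
network (and a fast surrogate oscillator with the same interface) to a
DDPG-style learner augmented with a predictive reward model and
Gumbel-Softmax exploration.  The control biomarker is beta-band (13-35 Hz)
power of GPi spiking.
"""

from .biomarker import (BetaBandSpec, BiomarkerConfig, ObservationWindow,
                        PsdEstimate, beta_power, estimate_psd,
                        raster_beta_power, spikes_to_signal)
from .config import EnvConfig, TrainConfig, load_config, save_config
from .raster import SpikeRaster
from .reward import RewardSpec, compute_reward

__all__ = [
    "BetaBandSpec", "BiomarkerConfig", "ObservationWindow", "PsdEstimate",
    "beta_power", "estimate_psd", "raster_beta_power", "spikes_to_signal",
    "EnvConfig", "TrainConfig", "load_config", "save_config",
    "SpikeRaster", "RewardSpec", "compute_reward",
    "make_env",
]

__version__ = "0.1.0"


def make_env(config: EnvConfig):
    """Build the environment selected by ``config.backend``."""
    from .env.api import BGNetworkEnv, SurrogateEnv

    if config.backend == "surrogate":
        return SurrogateEnv(config)
    return BGNetworkEnv(config)
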