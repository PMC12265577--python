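"""Loading and validation of the basal-ganglia parameter file.

All neuron, synapse and stimulation constants live in one bundled YAML file
(`params/bg_default.yaml`) — the single versioned source of truth for the
network model.  The parameterization follows the single-compartment
conductance-model lineage used in computational DBS studies (fast Na/K spike
currents everywhere; low-threshold Ca, high-threshold Ca and Ca-dependent
AHP currents in the subcortical nuclei), with the dopamine-depletion switch
expressed as condition-dependent bias currents, indirect-pathway weights and
rhythmic cortical/striatal drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "POPULATIONS",
    "PopulationSpec",
    "ConnectionSpec",
    "DBSPulseSpec",
    "NetworkParams",
    "load_params",
    "default_param_path",
]

POPULATIONS = ("CtxE", "CtxI", "StrD1", "StrD2", "STN", "GPe", "GPi", "Thal")
# transmitter roles: CtxE, STN, Thal release glutamate; all others GABA
_SOURCE_SIGN = {
    "CtxE": "excitatory", "CtxI": "inhibitory",
    "StrD1": "inhibitory", "StrD2": "inhibitory",
    "STN": "excitatory", "GPe": "inhibitory",
    "GPi": "inhibitory", "Thal": "excitatory",
}

# membrane/gating parameter names expected for every population, in the
# column order consumed by the integrator kernel
MEMBRANE_FIELDS = (
    "cm", "gl", "el", "gna", "ena", "gk", "ek",
    "gt", "gca", "eca", "gahp", "k1", "eps_ca", "kca",
    "theta_m", "sigma_m",
    "theta_h", "sigma_h", "phi_h", "tau_h0", "tau_h1", "theta_ht", "sigma_ht",
    "theta_n", "sigma_n", "phi_n", "tau_n0", "tau_n1", "theta_nt", "sigma_nt",
    "theta_a", "sigma_a",
    "theta_r", "sigma_r", "phi_r", "tau_r0", "tau_r1", "theta_rt", "sigma_rt",
    "theta_s", "sigma_s",
    "alpha_syn", "beta_syn", "theta_g", "sigma_g",
)
N_MEMBRANE = len(MEMBRANE_FIELDS)


@dataclass(frozen=True)
class PopulationSpec:
    """One population: name, size, membrane parameters and background drive."""

    name: str
    size: int
    intrinsic: dict          # MEMBRANE_FIELDS -> value
    i_app: float             # condition-resolved bias current, uA/cm^2
    noise: float             # background current noise amplitude
    osc_amp: float           # condition-resolved rhythmic drive amplitude
    osc_freq: float          # Hz

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise KeyError(f"unknown population {self.name!r}")
        if self.size < 1:
            raise ValueError(f"population {self.name} size must be >= 1")
        missing = [f for f in MEMBRANE_FIELDS if f not in self.intrinsic]
        if missing:
            raise KeyError(
                f"population {self.name} missing parameter(s): {missing}"
            )


@dataclass(frozen=True)
class ConnectionSpec:
    """One projection between populations.

    ``p`` = 1 means deterministic all-to-all; ``p`` < 1 draws each synapse
    independently.  ``weight`` is the total expected synaptic conductance a
    target neuron receives from the whole source population (mS/cm^2); the
    per-synapse conductance is weight / (p * n_source).
    """

    source: str
    target: str
    sign: str
    weight: float
    p: float = 1.0
    delay: float = 0.0  # ms

    def __post_init__(self) -> None:
        for nm in (self.source, self.target):
            if nm not in POPULATIONS:
                raise KeyError(f"unknown population {nm!r} in connection")
        if self.sign != _SOURCE_SIGN[self.source]:
            raise ValueError(
                f"{self.source}->{self.target} declared {self.sign} but "
                f"{self.source} is {_SOURCE_SIGN[self.source]}"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"connection probability must be in (0,1], got {self.p}")
        if self.weight < 0 or self.delay < 0:
            raise ValueError("weight and delay must be nonnegative")


@dataclass(frozen=True)
class DBSPulseSpec:
    """Stimulation pulse delivered identically to every STN neuron."""

    target: str = "STN"
    amplitude: float = 300.0  # uA/cm^2
    width: float = 0.3        # ms, total (biphasic: half cathodic, half anodic)
    shape: str = "biphasic"

    def __post_init__(self) -> None:
        if self.target not in POPULATIONS:
            raise KeyError(f"unknown DBS target {self.target!r}")
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("pulse amplitude and width must be positive")
        if self.shape not in ("monophasic", "biphasic"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")


@dataclass(frozen=True)
class NetworkParams:
    """Fully resolved parameter set for one condition."""

    populations: tuple          # PopulationSpec, in POPULATIONS order
    connections: tuple          # ConnectionSpec
    dbs: DBSPulseSpec
    normalization: float        # biomarker scale (see biomarker module)
    esyn_exc: float = 0.0
    esyn_inh: float = -85.0

    @property
    def sizes(self) -> dict:
        return {p.name: p.size for p in self.populations}


def default_param_path() -> Path:
    return Path(resources.files("seadbs.env") / "params" / "bg_default.yaml")


def _resolve(value, condition: str):
    """Scalars pass through; {healthy: x, parkinsonian: y} maps resolve."""
    if isinstance(value, dict):
        if condition not in value:
            raise KeyError(f"condition {condition!r} missing from {value}")
        return float(value[condition])
    return float(value)


def load_params(condition: str, path: str | Path | None = None,
                population_size: int | None = None) -> NetworkParams:
    """Read the parameter file and resolve it for one disease condition."""
    path = Path(path) if path is not None else default_param_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    missing = [p for p in POPULATIONS if p not in raw.get("populations", {})]
    if missing:
        raise KeyError(f"parameter file {path} missing population(s): {missing}")

    defaults = dict(raw.get("membrane_defaults", {}))
    pops = []
    for name in POPULATIONS:
        d = {**defaults, **raw["populations"][name]}
        size = int(d.pop("size", 10))
        if population_size is not None:
            size = population_size
        osc = d.pop("osc", {"amp": 0.0, "freq": 0.0})
        spec = PopulationSpec(
            name=name,
            size=size,
            intrinsic={f: float(d[f]) for f in MEMBRANE_FIELDS if f in d},
            i_app=_resolve(d.get("i_app", 0.0), condition),
            noise=_resolve(d.get("noise", 0.0), condition),
            osc_amp=_resolve(osc.get("amp", 0.0), condition),
            osc_freq=float(osc.get("freq", 0.0)),
        )
        pops.append(spec)

    conns = []
    for c in raw.get("connections", []):
        c = dict(c)
        c["weight"] = _resolve(c["weight"], condition)
        conns.append(ConnectionSpec(**c))

    dbs = DBSPulseSpec(**raw.get("dbs", {}))
    norm = float(raw.get("biomarker", {}).get("normalization", 1.0))
    return NetworkParams(tuple(pops), tuple(conns), dbs, norm)
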