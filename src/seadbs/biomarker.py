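"""Beta-band power extraction from GPi spike rasters, and the windowed RL state.

Pipeline: a spike raster is discretised into per-neuron spike-count signals
(bin width 0.5 ms, i.e. 2 kHz sampling), a power spectral density is estimated
per neuron (Welch by default), the PSD is integrated over the beta band
(13-35 Hz) and averaged over neurons, and the resulting scalar ``P_beta`` is
pushed into a fixed-length FIFO observation window whose arithmetic mean is
the quantity the reward thresholds.

Beta-band resolution requires far more signal than one 2 ms control step or
one 60 ms episode (a single beta cycle lasts 29-77 ms), so the environment
maintains a persistent rolling raster (default 512 ms) from which the PSD is
re-estimated after every control step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .raster import SpikeRaster

__all__ = [
    "BetaBandSpec",
    "BiomarkerConfig",
    "PsdEstimate",
    "ObservationWindow",
    "spikes_to_signal",
    "estimate_psd",
    "beta_power",
    "raster_beta_power",
]


@dataclass(frozen=True)
class BetaBandSpec:
    """Frequency band treated as the pathological biomarker (Hz)."""

    low: float = 13.0
    high: float = 35.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class BiomarkerConfig:
    """How spike rasters become beta power.

    Attributes
    ----------
    bin_width : float
        Spike-count bin width in ms (0.5 ms -> 2 kHz effective sampling).
    method : str
        'welch' (Hann window, 50% overlap) or 'periodogram' (boxcar, no
        detrending -- the form that matches a plain DFT periodogram).
    segment : float
        Welch segment length in ms; must cover at least one cycle at the
        band's low edge.
    normalization : float
        Scale applied to the band-integrated, neuron-averaged power so that
        the unstimulated parkinsonian network sits near the 0.35 reward
        threshold.  Raw spike-count band power is left untouched at 1.0.
    band : BetaBandSpec
    """

    bin_width: float = 0.5
    method: str = "welch"
    segment: float = 256.0
    normalization: float = 1.0
    band: BetaBandSpec = field(default_factory=BetaBandSpec)

    def __post_init__(self) -> None:
        if not (0 < self.bin_width <= 1.0):
            raise ValueError(f"bin width must be in (0, 1] ms, got {self.bin_width}")
        if self.method not in ("welch", "periodogram"):
            raise ValueError(f"unknown PSD method {self.method!r}")
        if self.segment < 1000.0 / self.band.low:
            raise ValueError(
                f"segment {self.segment} ms shorter than one cycle at "
                f"{self.band.low} Hz ({1000.0 / self.band.low:.1f} ms)"
            )

    @property
    def fs(self) -> float:
        """Effective sampling rate of the binned signal, Hz."""
        return 1000.0 / self.bin_width


@dataclass
class PsdEstimate:
    """One-sided PSD on a strictly increasing frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (..., n_freqs), nonnegative

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD has negative entries")
        self.power = np.clip(self.power, 0.0, None)


def spikes_to_signal(raster: SpikeRaster, bin_width: float = 0.5) -> np.ndarray:
    """Discretise a raster into per-neuron spike-count series.

    Returns an array of shape ``(n_neurons, n_bins)`` where entry ``[j, k]``
    counts neuron ``j``'s spikes in ``[t0 + k*bin, t0 + (k+1)*bin)``.
    """
    if not (0 < bin_width <= 1.0):
        raise ValueError(f"bin width must be in (0, 1] ms, got {bin_width}")
    n_bins = int(round(raster.duration / bin_width))
    if n_bins == 0:
        raise ValueError("raster window shorter than one bin: zero-length signal")
    edges = raster.t0 + bin_width * np.arange(n_bins + 1)
    out = np.zeros((raster.n_neurons, n_bins))
    for j, s in enumerate(raster.spikes):
        if s.size:
            out[j], _ = np.histogram(s, bins=edges)
    return out


def estimate_psd(
    signal: np.ndarray, fs: float, config: BiomarkerConfig = BiomarkerConfig()
) -> PsdEstimate:
    """One-sided PSD of one signal or a stack of signals (last axis = time).

    'periodogram' is the raw boxcar periodogram without detrending, exactly
    ``|DFT|^2 / (fs * N)`` with one-sided doubling; 'welch' mean-detrends each
    Hann-windowed segment and averages 50%-overlapping segments.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 2 * config.band.high:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve the band up to "
            f"{config.band.high} Hz (need >= {2 * config.band.high})"
        )
    if config.method == "periodogram":
        freqs, power = _sig.periodogram(x, fs=fs, window="boxcar", detrend=False)
    else:
        nperseg = int(round(config.segment * fs / 1000.0))
        if x.shape[-1] < nperseg:
            raise ValueError(
                f"signal length {x.shape[-1]} < segment length {nperseg} samples"
            )
        freqs, power = _sig.welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant",
        )
    return PsdEstimate(freqs, power)


def beta_power(
    psd: PsdEstimate,
    band: BetaBandSpec = BetaBandSpec(),
    normalization: float = 1.0,
) -> float:
    """Band-integrated power averaged over neurons, times a fixed scale.

    Each neuron's PSD is integrated over ``[band.low, band.high]`` by
    trapezoidal quadrature (band edges interpolated onto the grid), the
    integrals are averaged over neurons, and the result is multiplied by
    ``normalization``.
    """
    f, p = psd.freqs, np.atleast_2d(psd.power)
    if band.low < f[0] or band.high > f[-1]:
        raise ValueError(
            f"band [{band.low}, {band.high}] Hz outside grid [{f[0]}, {f[-1]}]"
        )
    inside = (f > band.low) & (f < band.high)
    grid = np.concatenate([[band.low], f[inside], [band.high]])
    vals = np.empty((p.shape[0], grid.size))
    for j in range(p.shape[0]):
        vals[j, 0] = np.interp(band.low, f, p[j])
        vals[j, -1] = np.interp(band.high, f, p[j])
        vals[j, 1:-1] = p[j, inside]
    integrals = np.trapezoid(vals, grid, axis=1)
    return float(normalization * integrals.mean())


def raster_beta_power(
    raster: SpikeRaster, config: BiomarkerConfig = BiomarkerConfig()
) -> float:
    """Full pipeline: raster -> binned signals -> PSD -> scaled band power."""
    sig = spikes_to_signal(raster, config.bin_width)
    psd = estimate_psd(sig, config.fs, config)
    return beta_power(psd, config.band, config.normalization)


@dataclass
class ObservationWindow:
    """FIFO window of the last ``n_obs`` beta-power values — the RL state.

    The reward and the policy both consume this window: the policy sees the
    ordered values (zero-padded at the oldest end until the window fills) and
    the reward thresholds their arithmetic mean.
    """

    n_obs: int = 5
    values: np.ndarray = None  # oldest -> newest, length == fill count
    fill_count: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.values is None:
            self.values = np.empty(0)
        self.values = np.asarray(self.values, dtype=float)
        self.fill_count = len(self.values)

    def push(self, p_beta: float) -> None:
        """Append a beta-power value, evicting the oldest when full."""
        v = np.append(self.values, float(p_beta))
        if len(v) > self.n_obs:
            v = v[-self.n_obs:]
        self.values = v
        self.fill_count = len(v)

    @property
    def filled(self) -> bool:
        return self.fill_count >= self.n_obs

    @property
    def mean(self) -> float:
        """Arithmetic mean of the stored values (0 while empty)."""
        return float(self.values.mean()) if self.fill_count else 0.0

    def as_vector(self) -> np.ndarray:
        """Length-``n_obs`` state vector, zero-padded at the oldest end."""
        out = np.zeros(self.n_obs)
        if self.fill_count:
            out[self.n_obs - self.fill_count:] = self.values
        return out

    def copy(self) -> "ObservationWindow":
        return ObservationWindow(self.n_obs, self.values.copy())
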