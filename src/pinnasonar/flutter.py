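"""Flutter noise: structured covariance, simulated echo ensembles, estimators.

A fluttering target imposes stochastic amplitude modulations on successive
echoes.  The model treats these in dB as correlated Gaussian noise with a
structured covariance over the 14 binaural measurement slots: a per-slot
variance (sigma^2, default sigma = 5 dB as estimated from fluttering-insect
echoes), within-ear correlations that decay geometrically with position lag,
and a high correlation (default 0.9) between the two ears' simultaneous
measurements.

The estimation side mirrors how such a covariance is measured: ensonify the
target repeatedly, extract single-frequency spectral power per echo with the
Goertzel algorithm, and compute the standard deviation and lag correlations
of the dB gains.  ``simulate_flutter_echoes`` provides a synthetic ensemble
with known parameters for validating the estimators end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .sphere import Direction

__all__ = [
    "FlutterCovariance",
    "EchoEnsemble",
    "NOISE_LEVELS_DB",
    "LOCUST_ASPECT_ANGLES",
    "build_covariance",
    "simulate_flutter_echoes",
    "goertzel_power",
    "echo_gains_db",
    "estimate_sigma",
    "estimate_lag_correlation",
    "repetition_rate_hz",
]

#: Flutter-noise levels, dB std of the per-slot amplitude modulation.
NOISE_LEVELS_DB = {"low": 2.5, "medium": 5.0, "high": 7.5}

#: Aspect angles (azimuth, elevation) used when ensonifying a fluttering
#: target from several directions to check aspect independence of sigma.
LOCUST_ASPECT_ANGLES = (
    Direction(35.0, 0.0),
    Direction(45.0, 30.0),
    Direction(45.0, -30.0),
    Direction(90.0, 0.0),
    Direction(-45.0, 0.0),
)


@dataclass(frozen=True)
class FlutterCovariance:
    """Covariance of the flutter modulation over the binaural template slots.

    ``matrix`` is ``(2n, 2n)`` in dB^2, ordered left-ear positions then
    right-ear positions.
    """

    sigma_db: float
    within_ear_lag_corr: float
    interaural_corr: float
    n_positions: int
    matrix: np.ndarray

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.matrix)


def build_covariance(
    sigma_db: float = 5.0,
    lag_corr: float = 0.2,
    interaural_corr: float = 0.9,
    n_positions: int = 7,
) -> FlutterCovariance:
    """Assemble the structured flutter covariance.

    Within each ear the correlation between positions i and j is
    ``lag_corr**|i-j|`` (stationary geometric decay); between the ears the
    whole within-ear structure is scaled by ``interaural_corr``, so the
    same-position interaural covariance is ``interaural_corr * sigma^2``.
    The diagonal is ``sigma^2``.  The result is validated to be symmetric
    positive semi-definite.
    """
    if not abs(lag_corr) <= 1.0:
        raise ValueError("|lag_corr| must be <= 1")
    if not 0.0 <= interaural_corr <= 1.0:
        raise ValueError("interaural_corr must be in [0, 1]")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    r = toeplitz(np.asarray(lag_corr, dtype=float) ** np.arange(n_positions))
    ears = np.array([[1.0, interaural_corr], [interaural_corr, 1.0]])
    matrix = sigma_db**2 * np.kron(ears, r)
    min_eig = float(np.linalg.eigvalsh(matrix).min())
    if min_eig < -1e-9 * max(sigma_db**2, 1.0):
        raise ValueError(
            f"parameters give a non-PSD covariance (smallest eigenvalue {min_eig:.3g})"
        )
    return FlutterCovariance(sigma_db, lag_corr, interaural_corr, n_positions, matrix)


@dataclass(frozen=True)
class EchoEnsemble:
    """A sequence of echo traces from repeated ensonification of one target."""

    traces: np.ndarray  # (n_echoes, n_samples) pressure traces
    sampling_rate_hz: float
    carrier_khz: float
    aspect_angle: Direction | None = None

    @property
    def n_echoes(self) -> int:
        return self.traces.shape[0]


def simulate_flutter_echoes(
    n: int,
    sigma_db: float,
    lag_corr: float,
    carrier_khz: float = 40.0,
    sampling_rate_hz: float = 500_000.0,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 1.5e-3,
    aspect_angle: Direction | None = None,
) -> EchoEnsemble:
    """Simulate echoes from a fluttering target as amplitude-modulated bursts.

    Each echo is a tone burst at ``carrier_khz`` whose amplitude in dB
    follows a stationary AR(1) Gaussian sequence with standard deviation
    ``sigma_db`` and lag-1 correlation ``lag_corr`` across successive echoes.
    """
    if n < 2:
        raise ValueError("need at least 2 echoes")
    if sampling_rate_hz <= 2.0 * carrier_khz * 1e3:
        raise ValueError("sampling rate must exceed twice the carrier frequency")
    rng = np.random.default_rng(rng)
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = z[0]
    scale = np.sqrt(max(1.0 - lag_corr**2, 0.0))
    for i in range(1, n):
        x[i] = lag_corr * x[i - 1] + scale * z[i]
    gains_db = sigma_db * x  # stationary, mean 0, std sigma_db
    t = np.arange(int(round(duration_s * sampling_rate_hz))) / sampling_rate_hz
    burst = np.sin(2.0 * np.pi * carrier_khz * 1e3 * t)
    amps = 10.0 ** (gains_db / 20.0)
    return EchoEnsemble(amps[:, None] * burst[None, :], sampling_rate_hz, carrier_khz,
                        aspect_angle)


def goertzel_power(
    trace: np.ndarray, target_khz: float, sampling_rate_hz: float
) -> float:
    """Spectral power at a single frequency via the Goertzel recursion.

    Returns the squared magnitude of the DFT bin nearest ``target_khz``,
    identical to ``|fft(trace)[k]|**2`` but computed with the two-multiplier
    recursion that needs no full transform.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be a 1-D array of length >= 2")
    if target_khz * 1e3 >= sampling_rate_hz / 2.0:
        raise ValueError("target frequency must be below the Nyquist frequency")
    n = trace.size
    k = int(round(target_khz * 1e3 * n / sampling_rate_hz))
    w = 2.0 * np.pi * k / n
    coeff = 2.0 * np.cos(w)
    s_prev = s_prev2 = 0.0
    for sample in trace:
        s = sample + coeff * s_prev - s_prev2
        s_prev2 = s_prev
        s_prev = s
    return float(s_prev**2 + s_prev2**2 - coeff * s_prev * s_prev2)


def echo_gains_db(ensemble: EchoEnsemble, frequency_khz: float) -> np.ndarray:
    """Per-echo gain (dB) at one frequency: 10*log10 of the Goertzel power."""
    powers = np.array(
        [
            goertzel_power(tr, frequency_khz, ensemble.sampling_rate_hz)
            for tr in ensemble.traces
        ]
    )
    return 10.0 * np.log10(np.maximum(powers, np.finfo(float).tiny))


def estimate_sigma(ensemble: EchoEnsemble, frequency_khz: float) -> float:
    """Standard deviation (dB) of the per-echo spectral gains at one frequency."""
    if ensemble.n_echoes < 2:
        raise ValueError("need at least 2 echoes")
    return float(np.std(echo_gains_db(ensemble, frequency_khz), ddof=1))


def estimate_lag_correlation(
    ensemble: EchoEnsemble, frequency_khz: float, max_lag: int = 5
) -> np.ndarray:
    """Pearson correlation of the dB-gain sequence with its lagged copy.

    Returns one value per lag 1..max_lag.  A constant ensemble has no
    defined correlation; NaN is returned with a warning.
    """
    if ensemble.n_echoes <= max_lag + 1:
        raise ValueError("need more echoes than max_lag + 1")
    g = echo_gains_db(ensemble, frequency_khz)
    out = np.empty(max_lag)
    if np.std(g) == 0.0:
        warnings.warn("constant echo gains: lag correlation undefined", stacklevel=2)
        out.fill(np.nan)
        return out
    for lag in range(1, max_lag + 1):
        out[lag - 1] = np.corrcoef(g[:-lag], g[lag:])[0, 1]
    return out


def repetition_rate_hz(interpulse_interval_s: float) -> float:
    """Call repetition rate implied by an interpulse interval (e.g. 6 ms -> ~166 Hz)."""
    if interpulse_interval_s <= 0:
        raise ValueError("interpulse interval must be positive")
    return 1.0 / interpulse_interval_s
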