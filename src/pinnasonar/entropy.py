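"""Bayesian template matching and Shannon-entropy information transfer.

The measurement model: an echo of unknown mean strength A (dB above the
detection floor) arriving from cell theta produces the binaural vector

    b = max(t_theta + A + eps, 0),       eps ~ N(0, Sigma_n)

where t_theta is the zero-mean template for the cell, Sigma_n the flutter
covariance, and the elementwise maximum with 0 models the detection floor:
modulations that push the echo below threshold are truncated.  Since the
floor sits at the noise level, A is the echo's signal-to-noise ratio.

The receiver evaluates a Gaussian likelihood of b about the floored mean
max(t + A, 0) per candidate cell, marginalizes A over a uniform prior
(nuisance strength), and forms the posterior over cells with a uniform
position prior.  The Shannon entropy of that posterior — in bits — is the
residual uncertainty about the echo's origin; its Monte-Carlo average over
simulated echoes (20 realizations by default) is the expected entropy per
cell, and averaging over cells gives the global information transfer per
frequency and SNR.  All accumulation is in log space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr
from scipy.special import logsumexp

from .flutter import FlutterCovariance
from .sphere import SpherePartition
from .templates import TemplateSet

__all__ = [
    "StrengthPrior",
    "MeasurementVector",
    "EntropyMap",
    "simulate_measurement",
    "log_likelihood",
    "likelihood",
    "marginal_likelihood",
    "posterior",
    "entropy",
    "expected_entropy",
    "entropy_map",
    "angular_resolution",
]


@dataclass(frozen=True)
class StrengthPrior:
    """Uniform prior over the unknown mean echo strength A (dB).

    The bat is assumed to have no prior knowledge of the fraction of
    impinging energy the target reflects, so every strength in
    ``[a_min, a_max]`` is equally likely; the marginalization integral is
    evaluated on a grid of ``grid_step`` dB with trapezoid end weights.
    """

    a_min_db: float = 0.0
    a_max_db: float = 50.0
    grid_step_db: float = 1.0

    def __post_init__(self) -> None:
        if self.a_min_db > self.a_max_db:
            raise ValueError("a_min_db must be <= a_max_db")
        if self.grid_step_db <= 0:
            raise ValueError("grid_step_db must be positive")

    @property
    def grid(self) -> np.ndarray:
        if self.a_min_db == self.a_max_db:
            return np.array([self.a_min_db])
        n = int(round((self.a_max_db - self.a_min_db) / self.grid_step_db))
        return np.linspace(self.a_min_db, self.a_max_db, n + 1)

    @property
    def log_weights(self) -> np.ndarray:
        """Log of normalized trapezoid quadrature weights (sum to 1)."""
        g = self.grid
        if g.size == 1:
            return np.array([0.0])
        w = np.ones(g.size)
        w[0] = w[-1] = 0.5
        return np.log(w / w.sum())


@dataclass(frozen=True)
class MeasurementVector:
    """A simulated floored binaural measurement with its ground truth."""

    values: np.ndarray
    true_cell: int
    true_strength_db: float
    frequency_khz: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("floored measurements cannot be negative")
        object.__setattr__(self, "values", v)


def _as_values(b) -> np.ndarray:
    return np.asarray(b.values if isinstance(b, MeasurementVector) else b, dtype=float)


def simulate_measurement(
    template: np.ndarray,
    a_db: float,
    cov: FlutterCovariance,
    rng: np.random.Generator | int | None = None,
    true_cell: int = -1,
    frequency_khz: float = float("nan"),
) -> MeasurementVector:
    """Draw one floored noisy measurement b = max(t + A + eps, 0)."""
    rng = np.random.default_rng(rng)
    template = np.asarray(template, dtype=float)
    eps = cov.cholesky() @ rng.standard_normal(template.size)
    values = np.maximum(template + a_db + eps, 0.0)
    return MeasurementVector(values, true_cell, a_db, frequency_khz)


def log_likelihood(
    b, template: np.ndarray, a_db: float, cov: FlutterCovariance
) -> float:
    """Log Gaussian density of b about the floored mean max(t + A, 0)."""
    bv = _as_values(b)
    mu = np.maximum(np.asarray(template, dtype=float) + a_db, 0.0)
    chol = np.linalg.cholesky(cov.matrix)
    y = np.linalg.solve(chol, bv - mu)
    m = bv.size
    return float(
        -0.5 * y @ y - 0.5 * m * np.log(2.0 * np.pi) - np.log(np.diag(chol)).sum()
    )


def likelihood(b, template: np.ndarray, a_db: float, cov: FlutterCovariance) -> float:
    """Gaussian density of b given cell template and echo strength A."""
    return float(np.exp(log_likelihood(b, template, a_db, cov)))


def marginal_likelihood(
    b, template: np.ndarray, cov: FlutterCovariance, prior: StrengthPrior
) -> float:
    """Likelihood with the nuisance strength A averaged over its uniform prior."""
    logs = np.array(
        [log_likelihood(b, template, a, cov) for a in prior.grid]
    )
    return float(np.exp(logsumexp(logs + prior.log_weights)))


class _PosteriorEngine:
    """Vectorized posterior evaluation for a full template set.

    Whitens templates and measurements with the flutter covariance Cholesky
    factor once, then evaluates all (cell x strength-grid) Gaussian
    log-densities for batches of measurements with a single matrix product.
    """

    def __init__(
        self,
        ts: TemplateSet,
        cov: FlutterCovariance,
        prior: StrengthPrior,
        dtype: np.dtype = np.float64,
    ) -> None:
        if cov.matrix.shape[0] != ts.n_elements:
            raise ValueError("covariance size does not match template length")
        self.ts = ts
        self.cov = cov
        self.prior = prior
        self._dtype = np.dtype(dtype)
        chol = np.linalg.cholesky(cov.matrix)
        self._linv = np.linalg.inv(chol)
        m = ts.n_elements
        self._log_norm = -0.5 * m * np.log(2.0 * np.pi) - np.log(np.diag(chol)).sum()
        grid = prior.grid
        # floored means for every (strength, cell): (nA, N, M), whitened
        mu = np.maximum(ts.templates[None, :, :] + grid[:, None, None], 0.0)
        self.n_a, self.n_cells = mu.shape[0], mu.shape[1]
        z = mu.reshape(-1, m) @ self._linv.T
        z_sq = np.einsum("ij,ij->i", z, z)
        # everything that does not depend on the measurement, per (A, cell)
        self._offset = (
            (-0.5 * z_sq + self._log_norm).reshape(self.n_a, self.n_cells)
            + prior.log_weights[:, None]
        ).astype(self._dtype)
        self._zt = np.ascontiguousarray(z.T, dtype=self._dtype)  # (M, nA*N)

    def log_marginals(self, b_batch: np.ndarray) -> np.ndarray:
        """Log marginal likelihood per cell for a batch of measurements.

        ``b_batch`` is ``(n_meas, M)``; returns ``(n_meas, n_cells)``.
        """
        zb = np.atleast_2d(b_batch) @ self._linv.T
        zb_sq = np.einsum("ij,ij->i", zb, zb)
        loglik = (zb.astype(self._dtype) @ self._zt).reshape(
            -1, self.n_a, self.n_cells
        )
        loglik += self._offset[None, :, :]
        # manual log-sum-exp over the strength grid (hot path)
        mx = loglik.max(axis=1)
        np.exp(loglik - mx[:, None, :], out=loglik)
        lm = mx + np.log(loglik.sum(axis=1))
        return lm.astype(np.float64) - 0.5 * zb_sq[:, None]

    def posteriors(self, b_batch: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Posterior over cells (uniform position prior) per measurement."""
        b_batch = np.atleast_2d(b_batch)
        out = np.empty((b_batch.shape[0], self.n_cells))
        for start in range(0, b_batch.shape[0], chunk):
            lm = self.log_marginals(b_batch[start : start + chunk])
            if np.any(np.all(np.isinf(lm) & (lm < 0), axis=1)):
                raise FloatingPointError("all log-likelihoods are -inf")
            out[start : start + chunk] = np.exp(
                lm - logsumexp(lm, axis=1, keepdims=True)
            )
        return out


def posterior(
    b, ts: TemplateSet, cov: FlutterCovariance, prior: StrengthPrior
) -> np.ndarray:
    """Posterior probability of each cell given one measurement.

    Uniform 1/N position prior; marginal likelihoods are computed in log
    space and normalized to sum to 1.
    """
    engine = _PosteriorEngine(ts, cov, prior)
    return engine.posteriors(_as_values(b)[None, :])[0]


def entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector, in bits (0*log0 = 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def expected_entropy(
    cell: int,
    ts: TemplateSet,
    cov: FlutterCovariance,
    a_db: float,
    n_realizations: int = 20,
    rng: np.random.Generator | int | None = None,
    prior: StrengthPrior | None = None,
) -> float:
    """Monte-Carlo expected posterior entropy for echoes from one cell.

    Averages the posterior entropy over ``n_realizations`` simulated
    measurements from the cell at strength ``a_db``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(rng)
    prior = prior or StrengthPrior()
    engine = _PosteriorEngine(ts, cov, prior)
    chol = cov.cholesky()
    eps = rng.standard_normal((n_realizations, ts.n_elements)) @ chol.T
    a_eff = a_db + ts.relative_gain_db[cell]  # received strength at this cell
    b = np.maximum(ts.templates[cell][None, :] + a_eff + eps, 0.0)
    post = engine.posteriors(b)
    return float(np.mean([entropy(row) for row in post]))


@dataclass(frozen=True)
class EntropyMap:
    """Expected entropy H-bar (bits) on a (cell, frequency, snr) grid."""

    data: xr.DataArray  # dims: cell, frequency_khz, snr_db
    partition: SpherePartition
    n_realizations: int

    def global_mean(self) -> xr.DataArray:
        """Mean expected entropy over cells, per (frequency, snr)."""
        return self.data.mean(dim="cell")

    def cell_range(self) -> xr.DataArray:
        """Worst-minus-best expected entropy over cells, per (frequency, snr)."""
        return self.data.max(dim="cell") - self.data.min(dim="cell")

    def snr_curve(self, frequency_khz: float) -> tuple[np.ndarray, np.ndarray]:
        """(snr grid, global mean entropy) for one frequency, for interpolation."""
        g = self.global_mean().sel(frequency_khz=frequency_khz)
        return g["snr_db"].values, g.values


def entropy_map(
    template_sets: dict[float, TemplateSet] | list[TemplateSet],
    cov: FlutterCovariance,
    a_grid_db: np.ndarray | None = None,
    n_realizations: int = 20,
    rng: np.random.Generator | int | None = None,
    prior: StrengthPrior | None = None,
) -> EntropyMap:
    """Expected entropy for every cell, frequency and echo strength.

    For each frequency and each strength on the grid, ``n_realizations``
    measurements are simulated from every cell and the posterior entropy is
    averaged per cell.  The grid strength is the SNR an echo would have at
    the frequency's best-served direction (the 0 dB normalization anchor);
    each cell receives it shifted down by its relative round-trip gain, so
    directions the sonar loop attenuates are floored earlier — the
    directivity trade-off the map is built to expose.
    """
    if isinstance(template_sets, dict):
        sets = [template_sets[f] for f in sorted(template_sets)]
    else:
        sets = sorted(template_sets, key=lambda t: t.frequency_khz)
    if not sets:
        raise ValueError("need at least one template set")
    a_grid = np.arange(0.0, 51.0, 5.0) if a_grid_db is None else np.asarray(a_grid_db, float)
    if a_grid.size == 0:
        raise ValueError("strength grid must be non-empty")
    rng = np.random.default_rng(rng)
    prior = prior or StrengthPrior()
    part = sets[0].partition
    n = part.n_cells
    freqs = [ts.frequency_khz for ts in sets]
    h = np.empty((n, len(sets), a_grid.size))
    for fi, ts in enumerate(sets):
        # single precision in the bulk map: the posterior is normalized per
        # measurement and the map is Monte-Carlo averaged, so float32
        # round-off is far below the sampling noise
        engine = _PosteriorEngine(ts, cov, prior, dtype=np.float32)
        chol = cov.cholesky()
        a_eff = ts.relative_gain_db  # received strength offset per cell, <= 0
        for ai, a in enumerate(a_grid):
            eps = rng.standard_normal((n_realizations, n, ts.n_elements)) @ chol.T
            b = np.maximum(
                ts.templates[None, :, :] + (a + a_eff)[None, :, None] + eps, 0.0
            )
            post = engine.posteriors(b.reshape(-1, ts.n_elements))
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.where(post > 0, np.log2(np.where(post > 0, post, 1.0)), 0.0)
            ent = -(post * logp).sum(axis=1).reshape(n_realizations, n)
            h[:, fi, ai] = ent.mean(axis=0)
    data = xr.DataArray(
        h,
        dims=("cell", "frequency_khz", "snr_db"),
        coords={"cell": np.arange(n), "frequency_khz": freqs, "snr_db": a_grid},
        name="expected_entropy_bits",
    )
    return EntropyMap(data, part, n_realizations)


def angular_resolution(h_bits: float, partition: SpherePartition) -> float:
    """Effective solid angle (sr) of the posterior: (2*pi/N) * 2**H.

    The solid angle of the number of equal-area cells that would be
    equiprobable at entropy H; 0 bits resolves a single cell, log2(N) bits
    the whole hemisphere.
    """
    h_max = np.log2(partition.n_cells)
    if not 0.0 <= h_bits <= h_max + 1e-9:
        raise ValueError(f"entropy must lie in [0, {h_max:.3f}] bits")
    return float(partition.cell_solid_angle_sr * 2.0**h_bits)
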