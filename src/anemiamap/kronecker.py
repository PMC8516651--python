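"""Separable space-time covariance: Matérn in space ⊗ AR1 in time.

The latent spatio-temporal process Z is a zero-mean Gaussian process whose
covariance factorises as ``ω² · Matérn(ν=2, κ) ⊗ AR1(ρ)``.  The Matérn scale
κ is tied to the practical range δ by κ = √(8ν)/δ, with δ interpreted as the
distance (in degrees, Euclidean on lon/lat) at which correlation falls to
roughly 0.1.  All heavy operations (solve, log-determinant, quadratic form,
sampling) work on the eigendecompositions of the two factors and never
materialise the dense Kronecker product; a ``dense()`` method exists for
oracle checks on small instances.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv

__all__ = [
    "GPHyperparameters",
    "compute_kappa",
    "matern_correlation",
    "ar1_correlation",
    "SpaceTimeCovariance",
]


def compute_kappa(nu: float, delta: float) -> float:
    """Matérn scale κ = √(8ν)/δ for practical range δ (degrees)."""
    if delta <= 0:
        raise ValueError("range delta must be positive")
    return float(np.sqrt(8.0 * nu) / delta)


@dataclasses.dataclass
class GPHyperparameters:
    """Covariance and random-effect variance parameters.

    omega2
        Marginal variance ω² of the space-time field (logit² units).
    delta
        Practical spatial range δ in degrees; correlation ≈ 0.1 at D = δ.
    nu
        Matérn smoothness; fixed at 2 rather than estimated.
    rho
        AR1 correlation ρ between adjacent years, |ρ| < 1.
    gamma2_country
        Variance γ² of the iid country intercepts.
    sigma2_nugget
        Variance σ² of the iid per-observation nugget.
    """

    omega2: float
    delta: float
    rho: float
    gamma2_country: float
    sigma2_nugget: float
    nu: float = 2.0

    def __post_init__(self) -> None:
        if min(self.omega2, self.gamma2_country, self.sigma2_nugget) <= 0:
            raise ValueError("variance parameters must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.delta <= 0:
            raise ValueError("range delta must be positive")

    @property
    def kappa(self) -> float:
        return compute_kappa(self.nu, self.delta)


def matern_correlation(distance, kappa: float, nu: float = 2.0) -> np.ndarray:
    """Matérn correlation (1/(Γ(ν)2^{ν-1})) (κD)^ν K_ν(κD); 1 at D = 0."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    scaled = kappa * d
    with np.errstate(invalid="ignore"):
        corr = (scaled**nu) * kv(nu, scaled) / (gamma_fn(nu) * 2 ** (nu - 1))
    return np.where(scaled == 0, 1.0, corr)


def ar1_correlation(n_times: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix ρ^{|k-j|} over ``n_times`` consecutive steps."""
    lags = np.abs(np.subtract.outer(np.arange(n_times), np.arange(n_times)))
    return rho**lags


class SpaceTimeCovariance:
    """ω² Matérn(knots) ⊗ AR1(years), with Kronecker-factored algebra.

    Vectors are ordered space-major: entry ``s * n_t + t`` is knot ``s`` at
    time ``t`` (C-order flattening of an ``(n_knots, n_times)`` array), which
    matches ``np.kron(spatial, temporal)``.
    """

    # tiny diagonal jitter keeping the spatial factor numerically PD
    JITTER = 1e-10

    def __init__(
        self,
        knots: np.ndarray,
        n_times: int,
        omega2: float,
        delta: float,
        rho: float,
        nu: float = 2.0,
    ):
        knots = np.atleast_2d(np.asarray(knots, dtype=float))
        if knots.shape[1] != 2:
            raise ValueError("knots must be an (n, 2) array of lon/lat")
        dists = np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=-1)
        if np.any(dists[~np.eye(len(knots), dtype=bool)] == 0):
            raise ValueError("duplicate knots make the spatial factor singular")
        if not abs(rho) < 1:
            raise ValueError("|rho| must be < 1")
        if omega2 <= 0 or delta <= 0:
            raise ValueError("omega2 and delta must be positive")

        self.n_space = len(knots)
        self.n_time = int(n_times)
        kappa = compute_kappa(nu, delta)
        spatial = omega2 * matern_correlation(dists, kappa, nu)
        spatial[np.diag_indices_from(spatial)] += self.JITTER * omega2
        temporal = ar1_correlation(self.n_time, rho)
        self._spatial = spatial
        self._temporal = temporal

        ws, Us = np.linalg.eigh(spatial)
        wt, Ut = np.linalg.eigh(temporal)
        if ws.min() <= 0 or wt.min() <= 0:
            raise np.linalg.LinAlgError(
                "space-time covariance is not positive definite"
            )
        self._ws, self._Us = ws, Us
        self._wt, self._Ut = wt, Ut
        # eigenvalues of the Kronecker product, as an (n_space, n_time) table
        self._eig = np.outer(ws, wt)

    @property
    def n(self) -> int:
        return self.n_space * self.n_time

    def dense(self) -> np.ndarray:
        """Materialised covariance; for oracles / small instances only."""
        return np.kron(self._spatial, self._temporal)

    def _rotate(self, x: np.ndarray, forward: bool) -> np.ndarray:
        """(Us ⊗ Ut)ᵀ x (forward) or (Us ⊗ Ut) x, via reshapes."""
        X = np.asarray(x, dtype=float).reshape(self.n_space, self.n_time, -1)
        if forward:
            Y = np.einsum("si,itk->stk", self._Us.T, np.einsum("tj,sjk->stk", self._Ut.T, X))
        else:
            Y = np.einsum("si,itk->stk", self._Us, np.einsum("tj,sjk->stk", self._Ut, X))
        return Y.reshape(self.n, -1) if np.ndim(x) > 1 else Y.ravel()

    def solve(self, x: np.ndarray) -> np.ndarray:
        """Σ⁻¹ x without forming Σ."""
        y = self._rotate(x, forward=True)
        scale = 1.0 / self._eig.reshape(-1)
        y = y * (scale[:, None] if y.ndim > 1 else scale)
        return self._rotate(y, forward=False)

    def logdet(self) -> float:
        return float(np.sum(np.log(self._eig)))

    def quad_form(self, x: np.ndarray) -> float:
        """xᵀ Σ⁻¹ x."""
        y = self._rotate(x, forward=True)
        return float(np.sum(y**2 / self._eig.reshape(-1)))

    def inv_dense(self) -> np.ndarray:
        """Dense precision from the factor eigendecompositions."""
        Ps = self._Us @ np.diag(1.0 / self._ws) @ self._Us.T
        Pt = self._Ut @ np.diag(1.0 / self._wt) @ self._Ut.T
        return np.kron(Ps, Pt)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draws from N(0, Σ), shape (size, n)."""
        z = rng.standard_normal((self.n, size))
        y = z * np.sqrt(self._eig.reshape(-1))[:, None]
        return self._rotate(y, forward=False).T

    def logpdf(self, x: np.ndarray) -> float:
        return -0.5 * (
            self.quad_form(x) + self.logdet() + self.n * np.log(2 * np.pi)
        )
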