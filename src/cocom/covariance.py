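"""Structured longitudinal covariance for paired abundance trajectories.

The dynamic mapping likelihood assumes one shared residual covariance for
the stacked vector (species A at T times; species B at T times),

    Sigma = [[Sigma_A, Sigma_AB], [Sigma_BA, Sigma_B]],

generated by a small set of structuring parameters Psi: per-species
variances, temporal correlation parameters, and one cross-species
correlation.  Three within-species structures are available:

  ar1   stationary AR(1) on the actual (possibly unequal) time spacings,
        corr(t_j, t_k) = rho ** |t_j - t_k| (rho is the per-hour
        correlation); the default.
  ad1   first-order antedependence (nonstationary AR(1) on measurement
        index): variance builds up along the series.
  arma11  stationary ARMA(1,1) on index lags: corr(k) = gamma * rho**(k-1).

The cross block couples the two species with correlation ``rho_cross`` and
the geometric mean of the two within-species correlation profiles, which
reduces to an exact Kronecker (separable) structure when the two species
share their temporal parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["CovarianceSpec", "build_sigma", "build_sigma_univariate", "fit_psi_ml"]

STRUCTURES = ("ar1", "ad1", "arma11")


@dataclass(frozen=True)
class CovarianceSpec:
    """Structuring parameters Psi of the stacked residual covariance."""

    structure_id: str = "ar1"
    var_a: float = 1.0
    var_b: float = 1.0
    rho_a: float = 0.5
    rho_b: float = 0.5
    rho_cross: float = 0.0
    gamma_a: float = 0.5  # lag-1 correlation, arma11 only
    gamma_b: float = 0.5

    def __post_init__(self):
        if self.structure_id not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure_id!r}; expected one of {STRUCTURES}")
        if self.var_a <= 0 or self.var_b <= 0:
            raise ValueError("variances must be positive")
        for name in ("rho_a", "rho_b", "rho_cross", "gamma_a", "gamma_b"):
            if abs(getattr(self, name)) >= 1.0:
                raise ValueError(f"|{name}| must be < 1")

    @property
    def n_params(self) -> int:
        base = 5  # var_a, var_b, rho_a, rho_b, rho_cross
        return base + (2 if self.structure_id == "arma11" else 0)


def _corr_matrix(structure: str, rho: float, gamma: float, times: np.ndarray) -> np.ndarray:
    T = len(times)
    idx = np.arange(T)
    if structure == "ar1":
        lags = np.abs(times[:, None] - times[None, :])
        return np.sign(rho) ** np.round(lags) * np.abs(rho) ** lags if rho < 0 else rho ** lags
    if structure == "ad1":
        # x_1 = e_1, x_t = rho x_{t-1} + e_t with unit innovations, then
        # rescaled to unit diagonal (correlation profile only)
        lags = np.abs(idx[:, None] - idx[None, :])
        mins = np.minimum(idx[:, None], idx[None, :])
        if abs(rho) < 1e-12:
            return np.eye(T)
        cum = (1.0 - rho ** (2 * (mins + 1))) / (1.0 - rho**2)
        cov = rho**lags * cum
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)
    # arma11 on index lags
    lags = np.abs(idx[:, None] - idx[None, :])
    corr = np.where(lags == 0, 1.0, gamma * rho ** np.maximum(lags - 1, 0))
    return corr


def build_sigma(spec: CovarianceSpec, times) -> np.ndarray:
    """Build the 2T x 2T stacked covariance implied by ``spec`` on ``times``.

    Positive definiteness is verified by Cholesky; a failing matrix gets one
    trace-scaled jitter (1e-10) retry before raising.
    """
    times = np.asarray(times, dtype=float)
    ra = _corr_matrix(spec.structure_id, spec.rho_a, spec.gamma_a, times)
    rb = _corr_matrix(spec.structure_id, spec.rho_b, spec.gamma_b, times)
    sa = spec.var_a * ra
    sb = spec.var_b * rb
    prod = ra * rb
    if spec.rho_cross != 0.0 and np.any(prod < -1e-12):
        raise ValueError(
            "cross-species block undefined for sign-mixed temporal correlations; "
            "use nonnegative rho_a, rho_b with a nonzero rho_cross"
        )
    cross = spec.rho_cross * np.sqrt(spec.var_a * spec.var_b) * np.sqrt(np.maximum(prod, 0.0))
    sigma = np.block([[sa, cross], [cross.T, sb]])
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + 1e-10 * np.trace(sigma) / sigma.shape[0] * np.eye(sigma.shape[0])
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"implied covariance is not positive definite for {spec}") from err
    return sigma


def build_sigma_univariate(spec: CovarianceSpec, times, species: str = "a") -> np.ndarray:
    """T x T within-species covariance block for one species ('a' or 'b')."""
    times = np.asarray(times, dtype=float)
    if species == "a":
        return spec.var_a * _corr_matrix(spec.structure_id, spec.rho_a, spec.gamma_a, times)
    if species == "b":
        return spec.var_b * _corr_matrix(spec.structure_id, spec.rho_b, spec.gamma_b, times)
    raise ValueError("species must be 'a' or 'b'")


def whitener(sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """(Wc, logdet) with Wc = L^{-1} lower-triangular so Sigma^{-1} = Wc' Wc."""
    L = np.linalg.cholesky(sigma)
    Wc = linalg.solve_triangular(L, np.eye(L.shape[0]), lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return Wc, logdet


def _gaussian_ml_obj(resids: np.ndarray, sigma: np.ndarray) -> float:
    """-2/n * loglik (up to the 2*pi constant) of centered residual rows."""
    n = resids.shape[0]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    z = linalg.solve_triangular(L, resids.T, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return logdet + float(np.sum(z * z)) / n


def fit_psi_ml(
    resids: np.ndarray,
    times,
    structure: str = "ar1",
    bivariate: bool = True,
    shared_rho: bool = True,
    x0: CovarianceSpec | None = None,
    n_restarts: int = 1,
) -> tuple[CovarianceSpec, float]:
    """Maximum-likelihood covariance-structuring parameters Psi.

    ``resids`` is (n, 2T) for bivariate (stacked species) residuals or
    (n, T) univariate.  Optimized by Nelder-Mead simplex over transformed
    parameters (log variances, atanh correlations), with one restart from a
    perturbed point.  Returns (spec, loglik).
    """
    resids = np.asarray(resids, dtype=float)
    times = np.asarray(times, dtype=float)
    n = resids.shape[0]
    T = len(times)
    if bivariate and resids.shape[1] != 2 * T:
        raise ValueError("bivariate residuals must be (n, 2T)")
    if not bivariate and resids.shape[1] != T:
        raise ValueError("univariate residuals must be (n, T)")
    arma = structure == "arma11"

    if x0 is None:
        va = float(np.var(resids[:, :T])) if bivariate else float(np.var(resids))
        vb = float(np.var(resids[:, T:])) if bivariate else va
        x0 = CovarianceSpec(structure_id=structure, var_a=max(va, 1e-8), var_b=max(vb, 1e-8),
                            rho_a=0.5, rho_b=0.5, rho_cross=0.1 if bivariate else 0.0)

    def pack(spec: CovarianceSpec) -> np.ndarray:
        # per-hour AR(1) rho is mapped through atanh on [0,1)
        v = [np.log(spec.var_a), np.arctanh(np.clip(spec.rho_a, -0.99, 0.99))]
        if arma:
            v.append(np.arctanh(np.clip(spec.gamma_a, -0.99, 0.99)))
        if bivariate:
            v += [np.log(spec.var_b), np.arctanh(np.clip(spec.rho_b, -0.99, 0.99))]
            if arma:
                v.append(np.arctanh(np.clip(spec.gamma_b, -0.99, 0.99)))
            v.append(np.arctanh(np.clip(spec.rho_cross, -0.99, 0.99)))
        return np.array(v)

    def _corr(x):
        # tanh saturates to +/-1.0 in floats for large |x|; keep strictly inside
        return float(np.clip(np.tanh(x), -0.999999, 0.999999))

    def unpack(x: np.ndarray) -> CovarianceSpec:
        i = 0
        va = float(np.exp(np.clip(x[i], -40, 40))); i += 1
        ra = _corr(x[i]); i += 1
        ga = 0.5
        if arma:
            ga = _corr(x[i]); i += 1
        vb, rb, gb, rc = va, ra, ga, 0.0
        if bivariate:
            vb = float(np.exp(np.clip(x[i], -40, 40))); i += 1
            rb = _corr(x[i]); i += 1
            if arma:
                gb = _corr(x[i]); i += 1
            rc = _corr(x[i]); i += 1
        if not shared_rho:
            pass  # rho_a and rho_b are already separate when bivariate
        return CovarianceSpec(structure_id=structure, var_a=va, var_b=vb,
                              rho_a=abs(ra), rho_b=abs(rb), rho_cross=rc,
                              gamma_a=ga, gamma_b=gb)

    def objective(x):
        spec = unpack(x)
        try:
            sigma = build_sigma(spec, times) if bivariate else build_sigma_univariate(spec, times)
        except ValueError:
            return np.inf
        return _gaussian_ml_obj(resids, sigma)

    best = None
    start = pack(x0)
    rng_starts = [start]
    for k in range(n_restarts):
        rng_starts.append(start + 0.3 * (-1.0) ** k * np.ones_like(start))
    for s in rng_starts:
        sol = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if best is None or sol.fun < best.fun:
            best = sol
    spec = unpack(best.x)
    p = resids.shape[1]
    loglik = -0.5 * n * (best.fun + p * np.log(2.0 * np.pi))
    return spec, float(loglik)
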