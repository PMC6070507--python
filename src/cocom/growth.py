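"""Sigmoidal growth equations and Lotka-Volterra community dynamics.

This module covers single-species growth modeling (Gompertz, logistic and
Richards equations in the Zwietering parameterization, where ``r`` is the
tangent slope at the inflection point and ``lam`` the lag time) and the
two-species Lotka-Volterra (LV) competition/cooperation system

    dN_e/dt = r_e N_e (1 - (N_e + alpha_es N_s) / K_e)
    dN_s/dt = r_s N_s (1 - (N_s + alpha_se N_e) / K_s)

together with curve fitting, nested-model tests, AIC ranking, growth-phase
partitioning, decomposition of LV growth into independent and interactive
components, ecological interaction-type classification, and phenotypic
plasticity curves (co-culture minus monoculture growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthParams",
    "LVParams",
    "Trajectory",
    "GrowthDecomposition",
    "InteractionType",
    "LVBlowupError",
    "ConvergenceError",
    "eval_growth",
    "solve_lv",
    "decompose_lv",
    "fit_growth",
    "fit_lv",
    "f_test_nested",
    "select_by_aic",
    "partition_phases",
    "classify_interaction",
    "plasticity_curve",
    "gaussian_loglik",
    "STRATEGY_MATRIX",
]

GROWTH_MODELS = ("gompertz", "logistic", "richards")

#: Default fixed step (hours) for the fourth-order Runge-Kutta LV solver.
DEFAULT_RK4_STEP = 0.01


class LVBlowupError(RuntimeError):
    """LV integration left the physical domain (overflow or negative state)."""

    def __init__(self, time: float, state):
        self.time = float(time)
        self.state = state
        super().__init__(f"LV integration blew up at t={time:.4g} h (state={state})")


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one sigmoidal growth equation.

    A: asymptotic abundance; r: maximum specific growth rate (tangent at the
    inflection point, abundance units per hour); lam: lag time (h); v: shape
    parameter, Richards only.
    """

    model_id: str
    A: float
    r: float
    lam: float
    v: float | None = None

    def __post_init__(self):
        if self.model_id not in GROWTH_MODELS:
            raise ValueError(f"unknown model_id {self.model_id!r}; expected one of {GROWTH_MODELS}")
        for name in ("A", "r", "lam"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.model_id == "richards":
            if self.v is None or not np.isfinite(self.v) or self.v <= 0:
                raise ValueError(f"richards requires v > 0, got {self.v}")
        elif self.v is not None:
            raise ValueError(f"v is only meaningful for richards, got v={self.v} for {self.model_id}")

    @property
    def n_params(self) -> int:
        return 4 if self.model_id == "richards" else 3

    def as_array(self) -> np.ndarray:
        if self.model_id == "richards":
            return np.array([self.A, self.r, self.lam, self.v])
        return np.array([self.A, self.r, self.lam])


@dataclass(frozen=True)
class LVParams:
    """Six parameters of one genotype combination's coupled LV dynamics.

    r_e, r_s are Malthusian rates (1/h); K_e, K_s carrying capacities
    (abundance units); alpha_es (effect of species s on e) and alpha_se
    are signed dimensionless interaction coefficients.
    """

    r_e: float
    K_e: float
    alpha_es: float
    r_s: float
    K_s: float
    alpha_se: float

    def __post_init__(self):
        for name in ("r_e", "K_e", "r_s", "K_s"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val}")
        for name in ("alpha_es", "alpha_se"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_e, self.K_e, self.alpha_es, self.r_s, self.K_s, self.alpha_se])

    @classmethod
    def from_array(cls, theta) -> "LVParams":
        return cls(*(float(x) for x in theta))


@dataclass
class Trajectory:
    """One strain's abundance time course."""

    times: np.ndarray
    values: np.ndarray
    species_tag: str = ""
    strain_id: str = ""
    treatment: str = "mono"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if self.treatment not in ("mono", "co"):
            raise ValueError(f"treatment must be 'mono' or 'co', got {self.treatment!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GrowthDecomposition:
    """LV growth split into independent (intrinsic logistic) and interactive parts.

    At every time, ``overall = independent + interactive`` up to integration
    tolerance; the interactive curve starts at zero, the independent curve at
    the initial abundance.
    """

    overall: Trajectory
    independent: Trajectory
    interactive: np.ndarray  # may be negative, so not a Trajectory
    times: np.ndarray = field(init=False)

    def __post_init__(self):
        self.interactive = np.asarray(self.interactive, dtype=float)
        if not (len(self.overall) == len(self.independent) == len(self.interactive)):
            raise ValueError("components must share one time grid")
        self.times = self.overall.times


@dataclass(frozen=True)
class InteractionType:
    """Cell of the 3x3 ecological strategy matrix indexed by per-species signs."""

    label: str
    sign_e: int
    sign_s: int


#: Strategy matrix mapping (sign of species-e interactive growth, sign of
#: species-s interactive growth) to the ecological interaction type.
STRATEGY_MATRIX = {
    (-1, -1): "antagonism",
    (-1, 0): "amensalism",
    (-1, 1): "parasitism",
    (0, -1): "amensalism",
    (0, 0): "independence",
    (0, 1): "commensalism",
    (1, -1): "parasitism",
    (1, 0): "commensalism",
    (1, 1): "mutualism",
}


# ---------------------------------------------------------------------------
# growth equations
# ---------------------------------------------------------------------------

def eval_growth(params: GrowthParams, t) -> np.ndarray:
    """Evaluate a sigmoidal growth equation N(t).

    Returns abundance at each time in ``t`` (scalar in, scalar-shaped array
    out).  All three forms rise from ~0 through an exponential phase of
    maximum slope ``r`` at the inflection point, reached after lag ``lam``,
    to the asymptote ``A``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    A, r, lam = params.A, params.r, params.lam
    if params.model_id == "gompertz":
        expo = np.clip(r * math.e / A * (lam - t) + 1.0, -700, 700)
        return A * np.exp(-np.exp(expo))
    if params.model_id == "logistic":
        expo = np.clip(4.0 * r / A * (lam - t) + 2.0, -700, 700)
        return A / (1.0 + np.exp(expo))
    # richards
    v = params.v
    expo = np.clip(r / A * (1.0 + v) ** (1.0 + 1.0 / v) * (lam - t), -700, 700)
    inner = 1.0 + v * math.exp(1.0 + v) * np.exp(expo)
    return A * inner ** (-1.0 / v)


# ---------------------------------------------------------------------------
# LV solving
# ---------------------------------------------------------------------------

def _lv_rhs(ne: float, ns: float, p: LVParams) -> tuple[float, float]:
    dne = p.r_e * ne * (1.0 - (ne + p.alpha_es * ns) / p.K_e)
    dns = p.r_s * ns * (1.0 - (ns + p.alpha_se * ne) / p.K_s)
    return dne, dns


def _solve_lv_dense(params: LVParams, n0_e, n0_s, t0, t1, step):
    """Fixed-step RK4 on a fine grid; returns (grid, Ne, Ns)."""
    from . import _kernels

    n_steps = max(1, int(math.ceil((t1 - t0) / step)))
    grid = t0 + (t1 - t0) * np.arange(n_steps + 1) / n_steps
    theta = params.as_array()
    out = _kernels.lv_rk4_dense(theta, float(n0_e), float(n0_s), float(t0), float(t1), n_steps)
    if np.any(~np.isfinite(out)):
        bad = int(np.argmax(np.any(~np.isfinite(out), axis=1)))
        raise LVBlowupError(grid[bad], out[max(bad - 1, 0)])
    return grid, out[:, 0], out[:, 1]


def solve_lv(
    params: LVParams,
    n0_e: float,
    n0_s: float,
    times: Sequence[float],
    step: float = DEFAULT_RK4_STEP,
) -> tuple[Trajectory, Trajectory]:
    """Solve the coupled LV system by fixed-step RK4.

    Integrates from ``times[0]`` with a fixed step (default 0.01 h) and
    linearly interpolates the dense solution onto ``times``.  Deterministic
    given inputs.  Raises :class:`LVBlowupError` with the offending time on
    overflow or a negative-state excursion.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if n0_e < 0 or n0_s < 0:
        raise ValueError("initial abundances must be >= 0")
    grid, ne, ns = _solve_lv_dense(params, n0_e, n0_s, times[0], times[-1], step)
    floor = -1e-9 * max(params.K_e, params.K_s)
    if ne.min() < floor or ns.min() < floor:
        bad = int(np.argmax((ne < floor) | (ns < floor)))
        raise LVBlowupError(grid[bad], (ne[bad], ns[bad]))
    vals_e = np.interp(times, grid, np.maximum(ne, 0.0))
    vals_s = np.interp(times, grid, np.maximum(ns, 0.0))
    return (
        Trajectory(times, vals_e, species_tag="e", treatment="co"),
        Trajectory(times, vals_s, species_tag="s", treatment="co"),
    )


def decompose_lv(
    params: LVParams,
    traj_e: Trajectory,
    traj_s: Trajectory,
    step: float = DEFAULT_RK4_STEP,
    check_tol: float = 1e-3,
) -> tuple[GrowthDecomposition, GrowthDecomposition]:
    """Split solved LV trajectories into independent and interactive growth.

    The per-species growth rate is split as

        dN_e/dt = r_e N_e (1 - N_e/K_e)  +  r_e N_e (-alpha_es N_s / K_e)
                = dM_e (independent)     +  dN_e|s (interactive)

    and each term is integrated along the solved path on the RK4 grid
    (cumulative Simpson), so that overall = independent + interactive
    pointwise up to integration tolerance.  The trajectories must actually
    solve ``params``; a relative mismatch above ``check_tol`` is an error.
    """
    from scipy.integrate import cumulative_simpson

    if not np.array_equal(traj_e.times, traj_s.times):
        raise ValueError("trajectories must share a time grid")
    times = traj_e.times
    n0e, n0s = traj_e.values[0], traj_s.values[0]
    grid, ne, ns = _solve_lv_dense(params, n0e, n0s, times[0], times[-1], step)
    # consistency: the supplied trajectories must lie on the solved path
    scale = max(ne.max(), ns.max(), 1e-30)
    res_e = np.max(np.abs(np.interp(times, grid, ne) - traj_e.values))
    res_s = np.max(np.abs(np.interp(times, grid, ns) - traj_s.values))
    if max(res_e, res_s) > check_tol * scale:
        raise ValueError(
            "trajectories do not solve the given LVParams "
            f"(max residual {max(res_e, res_s):.3g} vs tolerance {check_tol * scale:.3g})"
        )

    mdot_e = params.r_e * ne * (1.0 - ne / params.K_e)
    idot_e = params.r_e * ne * (-params.alpha_es * ns / params.K_e)
    mdot_s = params.r_s * ns * (1.0 - ns / params.K_s)
    idot_s = params.r_s * ns * (-params.alpha_se * ne / params.K_s)

    def build(n0, mdot, idot, traj, tag):
        m_int = n0 + cumulative_simpson(mdot, x=grid, initial=0.0)
        i_int = cumulative_simpson(idot, x=grid, initial=0.0)
        independent = Trajectory(times, np.maximum(np.interp(times, grid, m_int), 0.0),
                                 species_tag=tag, treatment="co")
        interactive = np.interp(times, grid, i_int)
        return GrowthDecomposition(overall=traj, independent=independent, interactive=interactive)

    return (
        build(n0e, mdot_e, idot_e, traj_e, traj_e.species_tag),
        build(n0s, mdot_s, idot_s, traj_s, traj_s.species_tag),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _growth_residual_factory(model_id, times, values):
    if model_id == "richards":
        def resid(x):
            p = GrowthParams("richards", *np.maximum(x[:3], 1e-12), v=max(x[3], 1e-6))
            return eval_growth(p, times) - values
    else:
        def resid(x):
            p = GrowthParams(model_id, *np.maximum(x, 1e-12))
            return eval_growth(p, times) - values
    return resid


def _growth_starts(model_id, times, values):
    a0 = float(values.max())
    diffs = np.diff(values) / np.diff(times)
    r0 = float(diffs.max()) if np.any(diffs > 0) else a0 / max(times[-1] - times[0], 1.0)
    above = np.nonzero(values > 0.1 * a0)[0]
    lam_candidates = [0.0]
    if len(above):
        lam_candidates.append(float(times[above[0]]))
    starts = []
    for lam0 in lam_candidates:
        if model_id == "richards":
            for v0 in (0.5, 1.0, 2.0):
                starts.append([a0, r0, lam0, v0])
        else:
            starts.append([a0, r0, lam0])
    return starts


def fit_growth(traj: Trajectory, model_id: str, x0=None) -> tuple[GrowthParams, float, int]:
    """Nonlinear least-squares fit of one growth equation to a trajectory.

    Multi-start (lag from {0, first time above 10% of max}; A from the
    observed maximum; r from the maximum finite difference; v from
    {0.5, 1, 2}); returns the best (params, rss, n_obs).  A trajectory
    with no signal (essentially constant) or fewer than p+1 points is
    rejected.
    """
    if model_id not in GROWTH_MODELS:
        raise ValueError(f"unknown model_id {model_id!r}")
    times, values = traj.times, traj.values
    n_par = 4 if model_id == "richards" else 3
    if len(times) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} observations to fit {model_id}")
    spread = values.max() - values.min()
    if spread <= 1e-10 * max(abs(values.max()), 1.0):
        raise ValueError("constant trajectory: no sigmoid signal to fit (rank-deficient)")

    resid = _growth_residual_factory(model_id, times, values)
    lower = [1e-12, 1e-12, 0.0] + ([1e-3] if n_par == 4 else [])
    upper = [np.inf, np.inf, float(times[-1])] + ([50.0] if n_par == 4 else [])
    starts = [list(x0)] if x0 is not None else _growth_starts(model_id, times, values)
    best = None
    for s in starts:
        s = np.clip(s, lower, upper)
        try:
            sol = optimize.least_squares(
                resid, s, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise ConvergenceError(f"{model_id} fit did not converge from any start")
    x = best.x
    if model_id == "richards":
        params = GrowthParams("richards", x[0], x[1], x[2], v=x[3])
    else:
        params = GrowthParams(model_id, x[0], x[1], x[2])
    rss = float(2.0 * best.cost)
    return params, rss, len(times)


def _logistic_ode_start(traj: Trajectory):
    """(r_malthusian, K) start from a Zwietering logistic fit; tolerant to failure."""
    try:
        p, _, _ = fit_growth(traj, "logistic")
        return 4.0 * p.r / p.A, p.A
    except Exception:
        a0 = max(traj.values.max(), 1.0)
        return 0.3, a0


def fit_lv(
    traj_e: Trajectory,
    traj_s: Trajectory,
    n0: tuple[float, float] | None = None,
    step: float = 0.1,
    alpha_starts: Iterable[float] = (-0.5, 0.0, 0.5),
) -> tuple[LVParams, float, float]:
    """Jointly fit the six LV parameters to a co-culture trajectory pair.

    Least squares with the RK4 solver embedded in the objective (fit-time
    step 0.1 h; refine with :func:`solve_lv` afterwards if needed).
    Starting values come from per-species logistic fits with the interaction
    coefficients initialized on a small grid around zero.  Returns
    (params, rss, gaussian loglik).
    """
    from . import _kernels

    if not np.array_equal(traj_e.times, traj_s.times):
        raise ValueError("trajectories must share a time grid")
    times = traj_e.times
    if n0 is None:
        n0 = (float(traj_e.values[0]), float(traj_s.values[0]))
    if n0[0] <= 0 or n0[1] <= 0:
        raise ValueError("fit_lv needs positive initial abundances")

    re0, ke0 = _logistic_ode_start(traj_e)
    rs0, ks0 = _logistic_ode_start(traj_s)
    scale_e = max(traj_e.values.max(), 1.0)
    scale_s = max(traj_s.values.max(), 1.0)
    obs = np.concatenate([traj_e.values / scale_e, traj_s.values / scale_s])

    times_rel = times - times[0]  # the kernel integrates from the first time

    def resid(u):
        theta = np.array([np.exp(u[0]), np.exp(u[1]), u[2], np.exp(u[3]), np.exp(u[4]), u[5]])
        curves = _kernels.lv_rk4_obs(theta, n0[0], n0[1], times_rel, step)
        if np.any(~np.isfinite(curves)):
            return np.full(2 * len(times), 1e6)
        model = np.concatenate([curves[:, 0] / scale_e, curves[:, 1] / scale_s])
        return model - obs

    best = None
    for a_es in alpha_starts:
        for a_se in alpha_starts:
            u0 = np.array([np.log(re0), np.log(ke0), a_es, np.log(rs0), np.log(ks0), a_se])
            try:
                sol = optimize.least_squares(resid, u0, xtol=1e-14, ftol=1e-14, max_nfev=4000)
            except Exception:
                continue
            if np.all(np.isfinite(sol.x)) and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise ConvergenceError("LV fit did not converge from any start")
    u = best.x
    params = LVParams(np.exp(u[0]), np.exp(u[1]), u[2], np.exp(u[3]), np.exp(u[4]), u[5])
    fit_e, fit_s = solve_lv(params, n0[0], n0[1], times, step=step)
    rss_e = float(np.sum((fit_e.values - traj_e.values) ** 2))
    rss_s = float(np.sum((fit_s.values - traj_s.values) ** 2))
    rss = rss_e + rss_s
    loglik = gaussian_loglik(rss_e, len(times)) + gaussian_loglik(rss_s, len(times))
    return params, rss, loglik


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood of a least-squares fit (sigma^2 = rss/n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def f_test_nested(fit_reduced, fit_full) -> tuple[float, float]:
    """F test of a reduced against a full nested least-squares fit.

    Each fit is a (params, rss, n_obs) triple as returned by
    :func:`fit_growth`.  F = ((RSS_r - RSS_f)/(p_f - p_r)) / (RSS_f/(n - p_f)).
    A full-model RSS above the reduced one (beyond numerical noise) means the
    full fit did not converge properly and is rejected.
    """
    pr_params, rss_r, n = fit_reduced
    pf_params, rss_f, n_f = fit_full
    if n != n_f:
        raise ValueError("both fits must use the same data")
    p_r, p_f = pr_params.n_params, pf_params.n_params
    if p_r >= p_f:
        raise ValueError("reduced model must have fewer parameters than the full model")
    if rss_f > rss_r * (1.0 + 1e-9):
        raise ValueError(
            "full-model RSS exceeds reduced-model RSS; refit the full model "
            "warm-started from the reduced fit"
        )
    rss_f_c = min(rss_f, rss_r)
    df1, df2 = p_f - p_r, n - p_f
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    if rss_f_c <= 0:
        return math.inf, 0.0
    F = ((rss_r - rss_f_c) / df1) / (rss_f_c / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


def compare_growth_models(traj: Trajectory, reduced_id: str, full_id: str = "richards"):
    """Fit both models (warm-starting the full one from the reduced fit) and F-test them."""
    fit_r = fit_growth(traj, reduced_id)
    fit_f = fit_growth(traj, full_id)
    if fit_f[1] > fit_r[1]:
        pr = fit_r[0]
        warm = [pr.A, pr.r, pr.lam] + ([1.0] if full_id == "richards" else [])
        fit_warm = fit_growth(traj, full_id, x0=warm)
        if fit_warm[1] < fit_f[1]:
            fit_f = fit_warm
    return fit_r, fit_f, f_test_nested(fit_r, fit_f)


def select_by_aic(fits: Sequence[tuple[str, float, int]]) -> list[tuple[str, float]]:
    """Rank fitted models by AIC = 2k - 2 loglik (ascending; ties to fewer params).

    ``fits`` is a collection of (model label, loglik, n_params) computed on
    identical data.  Returns [(label, aic), ...] best first.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty model collection")
    scored = [(label, 2.0 * k - 2.0 * ll, k) for label, ll, k in fits]
    scored.sort(key=lambda t: (t[1], t[2]))
    return [(label, aic) for label, aic, _ in scored]


# ---------------------------------------------------------------------------
# phases, interaction classification, plasticity
# ---------------------------------------------------------------------------

def partition_phases(params: GrowthParams, window: tuple[float, float] | None = None):
    """Lag/exponential/stationary phase boundaries by the tangent-line convention.

    The lag phase ends at the lag time ``lam`` (x-intercept of the inflection
    tangent); the exponential phase ends where that tangent reaches the
    asymptote, at ``lam + A/r``.  Both boundaries are clipped to the
    observation window when one is given.
    """
    if params.r <= 0:
        raise ValueError("r must be positive to define the tangent line")
    t_lag_end = params.lam
    t_exp_end = params.lam + params.A / params.r
    if window is not None:
        lo, hi = window
        t_lag_end = min(max(t_lag_end, lo), hi)
        t_exp_end = min(max(t_exp_end, lo), hi)
    return float(t_lag_end), float(max(t_exp_end, t_lag_end))


def interaction_integral(decomp: GrowthDecomposition) -> float:
    """Time integral of the interactive growth component (signed)."""
    return float(np.trapezoid(decomp.interactive, decomp.times))


def classify_interaction(
    decomp_e: GrowthDecomposition,
    decomp_s: GrowthDecomposition,
    tol: float | None = None,
) -> InteractionType:
    """Classify the ecological interaction from signed interactive growth.

    The per-species sign is the sign of the time-integrated interactive
    component; integrals smaller in magnitude than ``tol`` count as zero.
    ``tol`` defaults to 1% of the species' integrated overall growth.
    """
    if not np.array_equal(decomp_e.times, decomp_s.times):
        raise ValueError("decompositions must share a time grid")

    def signed(decomp):
        integral = interaction_integral(decomp)
        t = tol
        if t is None:
            t = 0.01 * abs(float(np.trapezoid(decomp.overall.values, decomp.times)))
        if abs(integral) < t:
            return 0
        return 1 if integral > 0 else -1

    se, ss = signed(decomp_e), signed(decomp_s)
    return InteractionType(label=STRATEGY_MATRIX[(se, ss)], sign_e=se, sign_s=ss)


def plasticity_curve(mono: Trajectory, co: Trajectory) -> Trajectory:
    """Phenotypic plasticity: pointwise co-culture minus monoculture abundance.

    Evaluated on the monoculture grid; the co-culture trajectory is linearly
    interpolated onto it when the grids differ.  The two time ranges must
    overlap the full monoculture grid.
    """
    if co.times[0] > mono.times[0] + 1e-9 or co.times[-1] < mono.times[-1] - 1e-9:
        raise ValueError("co-culture time range does not cover the monoculture grid")
    co_vals = np.interp(mono.times, co.times, co.values)
    diff = co_vals - mono.values
    out = Trajectory(mono.times, np.zeros_like(diff), species_tag=mono.species_tag,
                     strain_id=mono.strain_id, treatment="co")
    out.values = diff  # bypass the >=0 invariant: plasticity is signed
    return out
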