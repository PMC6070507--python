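"""Dynamic QTL mapping: functional mapping of monoculture growth and
systems mapping (CoCoM) of co-culture dynamics.

Functional mapping regresses whole growth trajectories on marker genotypes
by giving each genotype its own Richards (or Gompertz/logistic) mean curve
under a shared structured residual covariance; the marker is tested by the
likelihood ratio of genotype-specific versus shared curves.

Systems mapping replaces the single-species growth law with the coupled
Lotka-Volterra system, so each interspecific genotype combination (AB, Ab,
aB, ab) owns a six-parameter Theta = (r_e, K_e, alpha_e|s; r_s, K_s,
alpha_s|e) and the stacked trajectory pair of every strain pair enters a
four-component multivariate-normal mixture with a shared 2T x 2T structured
covariance.  The scan statistic is the LRT of "one shared Theta" against
combo-specific Thetas; genome-wide significance comes from permutation of
the phenotype pair-blocks against the genotype pairs.

Computational note: genome scans and permutations profile the residual
covariance at its estimate under the shared-curve null, which reduces each
marker (pair) to weighted curve fits of genotype-group mean trajectories;
:func:`systems_mapping_fit` performs the full alternating estimation
(EM posteriors / RK4-embedded curve ML / simplex covariance update) for a
single marker pair.  Abundances are modeled on log10 scale by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels, growth, quantgen
from .covariance import CovarianceSpec, build_sigma, build_sigma_univariate, fit_psi_ml, whitener
from .growth import GrowthParams, LVParams, ConvergenceError
from .static_mapping import GenotypePanel, MixtureWeights, filter_markers

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeComboParams",
    "DynamicFit",
    "FunctionalScanResult",
    "CocomScanResult",
    "DEFAULT_N0",
    "functional_mapping_scan",
    "systems_mapping_fit",
    "cocom_scan",
    "permutation_threshold",
    "test_effects",
    "effect_statistics",
    "genotype_curve_contrasts",
]

#: Design starting concentration of each species (copies/mL).
DEFAULT_N0 = 5e3

#: RK4 step (h) used inside scan objectives; single-pair estimation and
#: solve_lv use finer steps.
SCAN_RK4_STEP = 1.0
SYSTEMS_FIT_STEP = 0.25

_COMBO_BY_INDEX = {3: "AB", 2: "Ab", 1: "aB", 0: "ab"}  # index = 2*g_A + g_B


@dataclass
class GenotypeComboParams:
    """Combo-specific mean-model parameters plus shared initial abundances.

    For systems mapping ``thetas`` maps combo name -> LVParams; for
    functional mapping use ``growth_params`` mapping genotype (0/1) ->
    GrowthParams (per species).
    """

    thetas: dict = field(default_factory=dict)
    growth_params: dict = field(default_factory=dict)
    n0: tuple[float, float] = (DEFAULT_N0, DEFAULT_N0)


@dataclass
class DynamicFit:
    """Converged dynamic-mapping fit for one marker (pair)."""

    combo_params: GenotypeComboParams
    cov: CovarianceSpec
    loglik: float
    loglik_null: float
    lrt: float
    converged: bool
    n_iter: int
    times: np.ndarray
    mean_curves: dict = field(default_factory=dict)  # combo -> (2T,) modeling scale
    effects: quantgen.GeneticEffects | None = None
    log_scale: bool = True


@dataclass
class FunctionalScanResult:
    """Per-marker functional-mapping LRTs plus everything needed to permute."""

    lrt: np.ndarray
    marker_ids: np.ndarray
    cov: CovarianceSpec
    h0_params: np.ndarray  # kernel parameterization (log A, log r, lam, log v)
    group_params: np.ndarray  # (m, 2, 4)
    times: np.ndarray
    max_stat_fn: Callable = None
    threshold: float | None = None

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker": self.marker_ids, "lrt": self.lrt})
        if self.threshold is not None:
            df["significant"] = df["lrt"] > self.threshold
        return df

    def growth_params(self, marker_index: int) -> dict:
        """Genotype -> fitted GrowthParams (modeling scale) for one marker."""
        out = {}
        for g in (0, 1):
            u = self.group_params[marker_index, g]
            if np.all(np.isfinite(u)):
                out[g] = _u_to_growthparams(u)
        return out


@dataclass
class CocomScanResult:
    """Marker-pair LRT grid from the CoCoM systems-mapping scan."""

    lrt: np.ndarray  # (mA, mB)
    marker_ids_a: np.ndarray
    marker_ids_b: np.ndarray
    cov: CovarianceSpec
    h0_params: np.ndarray  # LV kernel parameterization (6,)
    combo_params_u: np.ndarray  # (mA, mB, 4, 6)
    times: np.ndarray
    n0: tuple[float, float] = (DEFAULT_N0, DEFAULT_N0)
    max_stat_fn: Callable = None
    threshold: float | None = None

    def table(self) -> pd.DataFrame:
        ja, jb = np.meshgrid(np.arange(len(self.marker_ids_a)),
                             np.arange(len(self.marker_ids_b)), indexing="ij")
        df = pd.DataFrame({
            "marker_a": np.asarray(self.marker_ids_a)[ja.ravel()],
            "marker_b": np.asarray(self.marker_ids_b)[jb.ravel()],
            "lrt": self.lrt.ravel(),
        }).sort_values("lrt", ascending=False, ignore_index=True)
        if self.threshold is not None:
            df["significant"] = df["lrt"] > self.threshold
        return df


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def to_model_scale(y: np.ndarray, log_scale: bool, ref: float = 1.0) -> np.ndarray:
    """log10 of abundance over a reference level (1.0 keeps absolute log10).

    Functional mapping models growth relative to the inoculum, log10(N/N0),
    the scale on which the sigmoidal growth laws rise from zero; systems
    mapping keeps absolute log10 because the LV dynamics carry N0 themselves.
    """
    y = np.asarray(y, dtype=float)
    if not log_scale:
        return y
    if np.any(y <= 0):
        raise ValueError("log10 modeling scale requires strictly positive abundances")
    return np.log10(y / ref)


def _richards_u0(ybar: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Warm start in kernel space from a bounded multi-start Richards fit."""
    traj = growth.Trajectory(times, np.maximum(ybar, 1e-9))
    p, _, _ = growth.fit_growth(traj, "richards")
    return np.array([math.log(p.A), math.log(p.r), p.lam, math.log(p.v)])


def _lv_u0(ybar2: np.ndarray, times: np.ndarray, n0: tuple[float, float],
           log_scale: bool) -> np.ndarray:
    """Warm start for the shared LV fit from per-species logistic fits.

    Grids too short for a sigmoid fit fall back to the Malthusian rate
    implied by the observed overall growth, r ~ ln(max/n0) / t_max."""
    T = len(times)
    raw_a = 10.0 ** ybar2[:T] if log_scale else ybar2[:T]
    raw_b = 10.0 ** ybar2[T:] if log_scale else ybar2[T:]
    t_max = max(times[-1], 1e-6)
    out = []
    for raw, n0_sp in ((raw_a, n0[0]), (raw_b, n0[1])):
        r0 = k0 = None
        if T >= 5:
            try:
                p, _, _ = growth.fit_growth(growth.Trajectory(times, np.maximum(raw, 0)),
                                            "logistic")
                r0, k0 = 4.0 * p.r / p.A, p.A
            except Exception:
                pass
        if r0 is None:
            k0 = float(np.max(raw)) * 1.05
            r0 = math.log(max(k0 / max(n0_sp, 1e-12), 1.001)) / t_max
        out += [math.log(max(r0, 1e-3)), math.log(max(k0, 1.0)), 0.0]
    return np.array(out)


def _u_to_lvparams(u: np.ndarray) -> LVParams:
    return LVParams(math.exp(u[0]), math.exp(u[1]), float(u[2]),
                    math.exp(u[3]), math.exp(u[4]), float(u[5]))


def _u_to_growthparams(u: np.ndarray) -> GrowthParams:
    return GrowthParams("richards", math.exp(u[0]), math.exp(u[1]),
                        max(float(u[2]), 0.0), v=math.exp(u[3]))


# ---------------------------------------------------------------------------
# functional mapping (monoculture)
# ---------------------------------------------------------------------------

def functional_mapping_scan(
    panel: GenotypePanel,
    abundance: np.ndarray,
    times,
    model_id: str = "richards",
    cov_structure: str = "ar1",
    log_scale: bool = True,
    n0: float = DEFAULT_N0,
    maf_min: float = 0.1,
    missing_max: float = 0.2,
) -> FunctionalScanResult:
    """Scan one species' markers against monoculture growth trajectories.

    Trajectories are modeled as log10(N/N0) (growth over the inoculum
    ``n0``), the scale on which the sigmoidal growth laws rise from zero.
    H1 gives each genotype its own Richards curve, H0 one shared curve; the
    residual covariance (structure ``cov_structure``) is estimated under H0
    and shared, so LRT = 2(l1 - l0) reduces to weighted mean-curve fits.
    Markers failing MAF/missingness filters are dropped; markers monomorphic
    after missing-data removal are skipped with NaN.
    """
    if model_id != "richards":
        raise NotImplementedError("the functional-mapping scan fits Richards mean curves")
    times = np.asarray(times, dtype=float)
    panel, _ = filter_markers(panel, maf_min, missing_max)
    Y = to_model_scale(abundance, log_scale, ref=n0 if log_scale else 1.0)
    n, T = Y.shape
    if T != len(times):
        raise ValueError("phenotype matrix and times disagree")

    ybar = Y.mean(axis=0)
    u0 = _richards_u0(ybar, times)
    # profile the covariance under the shared-curve null, then re-tighten the curve
    mu0 = _kernels.richards_curve_u(u0, times)
    spec, _ = fit_psi_ml(Y - mu0, times, structure=cov_structure, bivariate=False)
    sigma = build_sigma_univariate(spec, times)
    Wc, _ = whitener(sigma)
    u0, _ = _kernels.fit_richards_lm(ybar, times, Wc, u0)
    mu0 = _kernels.richards_curve_u(u0, times)

    G = np.ascontiguousarray(panel.calls)
    lrt, uhat = _kernels.fm_scan_lrt(Y, G, times, Wc, mu0, u0)

    def max_stat(perm_idx: np.ndarray) -> float:
        l, _ = _kernels.fm_scan_lrt(Y[perm_idx], G, times, Wc, mu0, u0)
        return float(np.nanmax(l))

    return FunctionalScanResult(
        lrt=lrt, marker_ids=panel.markers["marker_id"].to_numpy(),
        cov=spec, h0_params=u0, group_params=uhat, times=times,
        max_stat_fn=max_stat,
    )


# ---------------------------------------------------------------------------
# systems mapping (co-culture)
# ---------------------------------------------------------------------------

def _fit_h0_lv(Y2: np.ndarray, times: np.ndarray, n0, log_scale: bool,
               cov_structure: str, rk4_step: float):
    """Shared-curve LV fit plus covariance profile under the null."""
    T = len(times)
    ybar = Y2.mean(axis=0)
    u0 = _lv_u0(ybar, times, n0, log_scale)
    eye = np.eye(2 * T)
    u0, c = _kernels.fit_lv_lm(ybar, times, eye, u0, n0[0], n0[1], rk4_step, log_scale)
    if not np.isfinite(c):
        raise ConvergenceError("shared-curve LV fit failed")
    mu0 = _kernels.lv_curve_u(u0, times, n0[0], n0[1], rk4_step, log_scale)
    spec, _ = fit_psi_ml(Y2 - mu0, times, structure=cov_structure, bivariate=True)
    sigma = build_sigma(spec, times)
    Wc, _ = whitener(sigma)
    u0, _ = _kernels.fit_lv_lm(ybar, times, Wc, u0, n0[0], n0[1], rk4_step, log_scale)
    mu0 = _kernels.lv_curve_u(u0, times, n0[0], n0[1], rk4_step, log_scale)
    return u0, mu0, spec, Wc


def cocom_scan(
    panel_a: GenotypePanel,
    panel_b: GenotypePanel,
    abundance_a: np.ndarray,
    abundance_b: np.ndarray,
    times,
    n0: tuple[float, float] = (DEFAULT_N0, DEFAULT_N0),
    cov_structure: str = "ar1",
    log_scale: bool = True,
    maf_min: float = 0.1,
    missing_max: float = 0.2,
    rk4_step: float = SCAN_RK4_STEP,
) -> CocomScanResult:
    """Pairwise scan of markers from the two species' genomes (CoCoM).

    ``abundance_a``/``abundance_b`` are (n_pairs, T) co-culture trajectories
    aligned with the pairing of panel rows (row i of each panel belongs to
    strain pair i).  Tests H0: Theta_AB = Theta_Ab = Theta_aB = Theta_ab
    against combo-specific Thetas per marker pair.
    """
    times = np.asarray(times, dtype=float)
    panel_a, _ = filter_markers(panel_a, maf_min, missing_max)
    panel_b, _ = filter_markers(panel_b, maf_min, missing_max)
    Ya = to_model_scale(abundance_a, log_scale)
    Yb = to_model_scale(abundance_b, log_scale)
    Y2 = np.hstack([Ya, Yb])
    u0, mu0, spec, Wc = _fit_h0_lv(Y2, times, n0, log_scale, cov_structure, rk4_step)

    GA = np.ascontiguousarray(panel_a.calls)
    GB = np.ascontiguousarray(panel_b.calls)
    lrt, uhat = _kernels.cocom_scan_lrt(Y2, GA, GB, times, Wc, mu0, u0,
                                        n0[0], n0[1], rk4_step, log_scale)

    def max_stat(perm_idx: np.ndarray) -> float:
        l, _ = _kernels.cocom_scan_lrt(Y2[perm_idx], GA, GB, times, Wc, mu0, u0,
                                       n0[0], n0[1], rk4_step, log_scale)
        return float(np.nanmax(l))

    return CocomScanResult(
        lrt=lrt,
        marker_ids_a=panel_a.markers["marker_id"].to_numpy(),
        marker_ids_b=panel_b.markers["marker_id"].to_numpy(),
        cov=spec, h0_params=u0, combo_params_u=uhat, times=times, n0=n0,
        max_stat_fn=max_stat,
    )


def profile_combo_alphas(
    res: CocomScanResult,
    abundance_a: np.ndarray,
    abundance_b: np.ndarray,
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    log_scale: bool = True,
    rk4_step: float = SYSTEMS_FIT_STEP,
) -> dict:
    """Per-combo interaction coefficients conditional on the pooled growth fit.

    The free six-parameter combo fit walks a nearly flat (K, alpha) ridge --
    partner-induced saturation can mimic self-limitation -- so reported
    interaction coefficients come from this profile estimator: (r, K) of
    both species held at the shared-curve estimates, (alpha_e|s, alpha_s|e)
    refit per genotype combination.  Returns combo -> (alpha_es, alpha_se).
    """
    Ya = to_model_scale(abundance_a, log_scale)
    Yb = to_model_scale(abundance_b, log_scale)
    Y2 = np.hstack([Ya, Yb])
    Wc, _ = whitener(build_sigma(res.cov, res.times))
    out = {}
    for cidx, combo in _COMBO_BY_INDEX.items():
        rows = (2 * np.asarray(geno_a) + np.asarray(geno_b)) == cidx
        if rows.sum() < 2:
            out[combo] = (np.nan, np.nan)
            continue
        ybar = Y2[rows].mean(axis=0)
        a, cost = _kernels.fit_lv_alpha_lm(ybar, res.times, Wc, res.h0_params,
                                           res.n0[0], res.n0[1], rk4_step, log_scale)
        out[combo] = (float(a[0]), float(a[1])) if np.isfinite(cost) else (np.nan, np.nan)
    return out


def _mixture_loglik(Y2, mus, sigma, w):
    """Mixture log-likelihood over pairs given combo mean curves (4, 2T)."""
    n, p = Y2.shape
    L = np.linalg.cholesky(sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    logps = np.empty((n, 4))
    for c in range(4):
        z = np.linalg.solve(L, (Y2 - mus[c]).T)
        logps[:, c] = -0.5 * (np.sum(z * z, axis=0) + logdet + p * math.log(2 * math.pi))
    with np.errstate(divide="ignore"):
        joint = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf) + logps
    m = joint.max(axis=1, keepdims=True)
    ll = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
    resp = np.exp(joint - ll[:, None])
    return float(ll.sum()), resp


def systems_mapping_fit(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    abundance_a: np.ndarray,
    abundance_b: np.ndarray,
    times,
    weights: MixtureWeights | None = None,
    n0: tuple[float, float] = (DEFAULT_N0, DEFAULT_N0),
    cov_structure: str = "ar1",
    log_scale: bool = True,
    rk4_step: float = SYSTEMS_FIT_STEP,
    max_outer: int = 200,
    tol: float = 1e-6,
    shared_growth: bool = False,
) -> DynamicFit:
    """Full CoCoM estimation for one interspecific marker pair.

    Alternates (E) posterior combo memberships, (M1) per-combo LV parameters
    by RK4-embedded weighted Gaussian ML warm-started from the shared fit,
    and (M2) covariance-structuring parameters Psi by Nelder-Mead simplex,
    until the relative log-likelihood change drops below ``tol``.  With the
    default one-hot (marker-as-QTL) weights the E-step is trivial and the
    log-likelihood ascends monotonically.

    Returns a :class:`DynamicFit` whose effect curves come from the
    quantitative-genetic decomposition of the four fitted mean curves.
    """
    times = np.asarray(times, dtype=float)
    T = len(times)
    Ya = to_model_scale(abundance_a, log_scale)
    Yb = to_model_scale(abundance_b, log_scale)
    Y2 = np.hstack([Ya, Yb])
    n = Y2.shape[0]
    if weights is None:
        weights = MixtureWeights.one_hot(np.asarray(geno_a), np.asarray(geno_b))
    w = weights.w
    valid = ~np.any(np.isnan(w), axis=1)
    Y2, w = Y2[valid], w[valid]
    n = len(Y2)

    u_h0, mu0, spec, Wc = _fit_h0_lv(Y2, times, n0, log_scale, cov_structure, rk4_step)
    sigma = build_sigma(spec, times)
    loglik_null, _ = _mixture_loglik(Y2, np.tile(mu0, (4, 1)), sigma, w)

    u_c = np.tile(u_h0, (4, 1))
    mus = np.tile(mu0, (4, 1))
    loglik = -np.inf
    converged = False
    resp = w.copy()
    for it in range(1, max_outer + 1):
        # E step
        new_loglik, resp = _mixture_loglik(Y2, mus, sigma, w)
        # M1: combo LV parameters from responsibility-weighted mean curves;
        # with shared_growth only the interaction coefficients vary by combo
        for c in range(4):
            tot = resp[:, c].sum()
            if tot < 1e-9:
                continue
            ybar_c = resp[:, c] @ Y2 / tot
            if shared_growth:
                base = u_h0.copy()
                base[2], base[5] = u_c[c][2], u_c[c][5]
                a, cost = _kernels.fit_lv_alpha_lm(ybar_c, times, Wc, base,
                                                   n0[0], n0[1], rk4_step, log_scale)
                u_new = base.copy()
                u_new[2], u_new[5] = a[0], a[1]
            else:
                u_new, cost = _kernels.fit_lv_lm(ybar_c, times, Wc, u_c[c],
                                                 n0[0], n0[1], rk4_step, log_scale)
            if np.isfinite(cost):
                u_c[c] = u_new
                mus[c] = _kernels.lv_curve_u(u_c[c], times, n0[0], n0[1],
                                             rk4_step, log_scale)
        # M2: covariance structure from the posterior-weighted scatter.
        # sqrt(resp)-weighted rows reproduce S = sum_ic tau_ic r_ic r_ic' / n;
        # the factor 2 compensates for stacking 4 rows per pair (sum_c tau = 1).
        resid = np.concatenate([Y2 - mus[c] for c in range(4)])
        rw = 2.0 * np.sqrt(np.concatenate([resp[:, c] for c in range(4)]))
        spec, _ = fit_psi_ml(resid * rw[:, None], times, structure=cov_structure,
                             bivariate=True, x0=spec)
        sigma = build_sigma(spec, times)
        Wc, _ = whitener(sigma)
        if new_loglik - loglik < tol * (abs(loglik) + 1.0) and it > 2:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    # mixture components follow the weight-column order AB, Ab, aB, ab
    combo = GenotypeComboParams(
        thetas={quantgen.COMBO_ORDER[c]: _u_to_lvparams(u_c[c]) for c in range(4)},
        n0=n0,
    )
    curves = {quantgen.COMBO_ORDER[c]: mus[c] for c in range(4)}
    effects = quantgen.decompose_effects(quantgen.ComboValues(
        species_a=np.stack([mus[c][:T] for c in range(4)]),
        species_b=np.stack([mus[c][T:] for c in range(4)]),
    ))
    return DynamicFit(
        combo_params=combo, cov=spec, loglik=loglik, loglik_null=loglik_null,
        lrt=max(2.0 * (loglik - loglik_null), 0.0), converged=converged,
        n_iter=it, times=times, mean_curves=curves, effects=effects,
        log_scale=log_scale,
    )


# ---------------------------------------------------------------------------
# permutation thresholds and effect tests
# ---------------------------------------------------------------------------

def permutation_threshold(
    max_stat_fn: Callable[[np.ndarray], float],
    n: int,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    return_null: bool = False,
):
    """Genome-wide significance threshold by phenotype-block permutation.

    ``max_stat_fn`` maps a permutation of row indices (phenotype blocks
    shuffled against genotypes, keeping both species' trajectories of a pair
    together) to the per-permutation maximum scan statistic.  The threshold
    is the k-th largest null maximum with k = floor(alpha * (n_perm + 1)),
    the empirical (1 - alpha) quantile that makes "observed max > threshold"
    an exact level-alpha permutation test; seeded and bit-reproducible.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    k = int(alpha * (n_perm + 1))
    if k < 1:
        raise ValueError(
            f"alpha={alpha} is below the 1/(n_perm+1)={1.0 / (n_perm + 1):.3g} resolution")
    k = min(k, n_perm)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for j in range(n_perm):
        maxima[j] = max_stat_fn(rng.permutation(n))
    thr = float(np.sort(maxima)[n_perm - k])
    return (thr, maxima) if return_null else thr


def effect_statistics(effects: quantgen.GeneticEffects, times) -> dict:
    """Integrated squared effect curves, the test statistics of the effect tests."""
    t = np.asarray(times, dtype=float)

    def isq(curve):
        c = np.atleast_1d(curve)
        if len(c) == 1:
            return float(c[0] ** 2)
        return float(np.trapezoid(c**2, t))

    out = {
        "direct_a": isq(effects.direct_a),
        "direct_b": isq(effects.direct_b),
        "indirect_a_on_b": isq(effects.indirect_a_on_b),
        "indirect_b_on_a": isq(effects.indirect_b_on_a),
        "epistasis_a": isq(effects.epi_a),
        "epistasis_b": isq(effects.epi_b),
    }
    out["direct"] = out["direct_a"] + out["direct_b"]
    out["indirect"] = out["indirect_a_on_b"] + out["indirect_b_on_a"]
    out["epistasis"] = out["epistasis_a"] + out["epistasis_b"]
    return out


def test_effects(fit: DynamicFit, null_ensemble: Sequence[dict]) -> pd.DataFrame:
    """Permutation p-values for direct, indirect and genome-genome epistatic effects.

    ``null_ensemble`` is a sequence of :func:`effect_statistics` dicts
    computed on null (permuted) fits.  p = (1 + #{null >= observed}) /
    (1 + K); a zero effect curve gives statistic 0 and p = 1.
    """
    if not len(null_ensemble):
        raise ValueError("an empty null ensemble cannot calibrate the effect tests")
    obs = effect_statistics(fit.effects, fit.times)
    rows = []
    K = len(null_ensemble)
    for key, stat in obs.items():
        null_vals = np.array([d[key] for d in null_ensemble])
        if stat <= 0:
            p = 1.0
        else:
            p = (1.0 + np.sum(null_vals >= stat)) / (1.0 + K)
        rows.append({"effect": key, "statistic": stat, "p_value": float(p)})
    return pd.DataFrame(rows)


def genotype_curve_contrasts(curves_mono: dict, curves_co: dict) -> dict:
    """Treatment-wise genetic-effect curves and allelic sensitivity curves.

    ``curves_mono``/``curves_co`` map genotype code (0/1) to the fitted mean
    curve of the same marker in each treatment.  The effect curve within a
    treatment is half the genotype difference; the sensitivity curve of a
    genotype is its co-culture minus monoculture curve.
    """
    for d in (curves_mono, curves_co):
        if not (0 in d and 1 in d):
            raise ValueError("both genotypes must be fitted in both treatments")
    eff_mono = 0.5 * (np.asarray(curves_mono[1]) - np.asarray(curves_mono[0]))
    eff_co = 0.5 * (np.asarray(curves_co[1]) - np.asarray(curves_co[0]))
    sens = {g: np.asarray(curves_co[g]) - np.asarray(curves_mono[g]) for g in (0, 1)}
    return {
        "effect_mono": eff_mono,
        "effect_co": eff_co,
        "sensitivity": sens,
    }
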