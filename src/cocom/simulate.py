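"""Synthetic paired-community data emulating the co-culture study design,
plus the power / false-positive-rate simulation harness.

The generator reproduces the experiment's structure: n interspecific strain
pairs (default 45), abundance measured at 0, 2, ..., 24, 28, 32, 36 h with
three replicates, genotypes drawn i.i.d. at a given allele frequency, and
genotype(-combination)-specific mean dynamics -- Richards curves in
monoculture (direct effects only) and Lotka-Volterra dynamics in co-culture,
where combo-specific interaction coefficients induce direct, indirect and
genome-genome epistatic effects simultaneously.  Residuals are multivariate
normal with an AR(1)-structured covariance on the log10 abundance scale,
rescaled so the realized single-locus heritability at a reference time hits
the target.

Heritability is defined at the reference time (default: the observation
time of maximum between-combo variance) as the between-combo variance of
the mean curves over the total phenotypic variance of the
replicate-averaged data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import _kernels, dynamic_mapping, quantgen
from .covariance import CovarianceSpec, build_sigma, build_sigma_univariate
from .dataset import PairedCommunityDataset, PHENOTYPE_COLUMNS
from .growth import GrowthParams, LVParams, eval_growth
from .static_mapping import GenotypePanel

__all__ = ["SimScenario", "SimReport", "default_times", "simulate_dataset",
           "estimate_power_fpr"]


def default_times() -> np.ndarray:
    """The study's sampling grid: every 2 h to 24 h, then every 4 h to 36 h."""
    return np.concatenate([np.arange(0.0, 26.0, 2.0), [28.0, 32.0, 36.0]])


def _default_cov() -> CovarianceSpec:
    # log10-scale residual sd ~0.2 with strong hour-scale persistence
    return CovarianceSpec(structure_id="ar1", var_a=0.04, var_b=0.04,
                          rho_a=0.85, rho_b=0.85, rho_cross=0.2)


def _default_mono_params() -> dict:
    """Genotype -> per-species Richards curves of log10(N/N0) (direct effects only).

    Growth spans ~5 decades over the inoculum (5e3 -> ~1e9 copies/mL), with
    species A faster (shorter lag, steeper log-scale slope) than species B.
    """
    base_a = dict(A=5.3, r=0.55, lam=1.0, v=1.2)
    base_s = dict(A=5.0, r=0.42, lam=2.0, v=1.2)
    return {
        "a": {0: GrowthParams("richards", **base_a),
              1: GrowthParams("richards", **{**base_a, "A": 5.6})},
        "b": {0: GrowthParams("richards", **base_s),
              1: GrowthParams("richards", **{**base_s, "A": 5.3})},
    }


def _default_lv_base() -> LVParams:
    return LVParams(r_e=1.0, K_e=8.0e8, alpha_es=0.4, r_s=0.8, K_s=5.0e8, alpha_se=0.3)


@dataclass
class SimScenario:
    """One cell of the simulation design.

    ``h2`` is the target per-species heritability of the causal locus
    (pair) at the reference time; 0 gives a null dataset with no causal
    markers.  ``alpha_effects`` = (d_direct_a, d_direct_b, d_epistasis)
    are the shifts applied to the combo-specific interaction coefficients
    (alpha_e|s gains d1*x_A + d3*x_A*x_B, alpha_s|e gains d2*x_B +
    d3*x_A*x_B with x = +/-1), the minimal co-culture architecture carrying
    all three effect types for both species.
    """

    n_pairs: int = 45
    n_markers_a: int = 200
    n_markers_b: int = 200
    times: np.ndarray = field(default_factory=default_times)
    treatment: str = "co"
    h2: float = 0.0
    allele_freq: float = 0.5
    n_replicates: int = 3
    rep_noise_sd: float = 0.08  # per-replicate log10 measurement noise
    cov: CovarianceSpec = field(default_factory=_default_cov)
    n0: tuple = (dynamic_mapping.DEFAULT_N0, dynamic_mapping.DEFAULT_N0)
    causal_a: int | None = None  # defaults to the middle marker when h2 > 0
    causal_b: int | None = None
    mono_params: dict = field(default_factory=_default_mono_params)
    lv_base: LVParams = field(default_factory=_default_lv_base)
    alpha_effects: tuple = (0.12, 0.12, 0.12)
    ref_time: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("target heritability must lie in [0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if self.treatment not in ("mono", "co"):
            raise ValueError("treatment must be 'mono' or 'co'")
        for c, m in ((self.causal_a, self.n_markers_a), (self.causal_b, self.n_markers_b)):
            if c is not None and not 0 <= c < m:
                raise ValueError("causal marker index out of range")

    def causal_indices(self) -> tuple[int | None, int | None]:
        if self.h2 <= 0:
            return None, None
        ca = self.causal_a if self.causal_a is not None else self.n_markers_a // 2
        cb = self.causal_b if self.causal_b is not None else self.n_markers_b // 2
        return ca, cb


@dataclass
class SimReport:
    """Power/FPR summary of one scenario x method cell."""

    method: str
    treatment: str
    power: float | None
    fpr: float | None
    n_replicates: int
    seed: int
    threshold_alpha: float
    param_bias: pd.DataFrame | None = None
    detections: np.ndarray | None = None


# ---------------------------------------------------------------------------
# mean-curve construction
# ---------------------------------------------------------------------------

def combo_lv_params(scenario: SimScenario) -> dict:
    """Combo -> LVParams implied by the scenario's alpha-shift architecture."""
    d1, d2, d3 = scenario.alpha_effects
    base = scenario.lv_base
    out = {}
    for combo, (xa, xb) in zip(quantgen.COMBO_ORDER, ((1, 1), (1, -1), (-1, 1), (-1, -1))):
        out[combo] = LVParams(
            r_e=base.r_e, K_e=base.K_e,
            alpha_es=base.alpha_es + d1 * xa + d3 * xa * xb,
            r_s=base.r_s, K_s=base.K_s,
            alpha_se=base.alpha_se + d2 * xb + d3 * xa * xb,
        )
    return out


def co_mean_curves(scenario: SimScenario) -> dict:
    """Combo -> stacked (2T,) log10 mean curves from the LV architecture."""
    times = scenario.times
    curves = {}
    for combo, params in combo_lv_params(scenario).items():
        sol = _kernels.lv_rk4_obs(params.as_array(), scenario.n0[0], scenario.n0[1],
                                  times, 0.05)
        if np.any(~np.isfinite(sol)):
            raise ValueError(f"LV mean dynamics blew up for combo {combo}")
        curves[combo] = np.concatenate([np.log10(np.maximum(sol[:, 0], 1e-12)),
                                        np.log10(np.maximum(sol[:, 1], 1e-12))])
    return curves


def mono_mean_curves(scenario: SimScenario) -> dict:
    """(species, genotype) -> (T,) log10(N/N0) mean curves in monoculture."""
    out = {}
    for sp in ("a", "b"):
        for g in (0, 1):
            out[(sp, g)] = eval_growth(scenario.mono_params[sp][g], scenario.times)
    return out


def _reference_index(times: np.ndarray, curves: np.ndarray, ref_time) -> int:
    """Index of the reference time (default: max between-curve variance)."""
    if ref_time is not None:
        return int(np.argmin(np.abs(times - ref_time)))
    return int(np.argmax(curves.var(axis=0)))


def _residual_scale(vg: float, h2: float, base_var: float, rep_var: float,
                    n_rep: int) -> float:
    """Factor c with Vg / (Vg + c*(base_var + rep_var/n_rep)) = h2."""
    if h2 <= 0:
        return 1.0
    if vg <= 0:
        raise ValueError("unattainable heritability: effect sizes are zero but h2 > 0")
    target_res = vg * (1.0 - h2) / h2
    return target_res / (base_var + rep_var / n_rep)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _draw_panel(rng, n, m, freq, prefix) -> GenotypePanel:
    calls = (rng.random((n, m)) < freq).astype(np.int8)
    markers = pd.DataFrame({"marker_id": [f"{prefix}{j + 1}" for j in range(m)],
                            "pos": np.arange(1, m + 1) * 1000})
    strains = [f"{prefix}S{i + 1}" for i in range(n)]
    return GenotypePanel(markers, calls, strains, species_tag=prefix)


def simulate_dataset(scenario: SimScenario, seed: int | None = None) -> PairedCommunityDataset:
    """Draw one fully seed-reproducible dataset under the scenario."""
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, times = scenario.n_pairs, scenario.times
    T = len(times)
    panel_a = _draw_panel(rng, n, scenario.n_markers_a, scenario.allele_freq, "E")
    panel_b = _draw_panel(rng, n, scenario.n_markers_b, scenario.allele_freq, "S")
    pairs = pd.DataFrame({
        "pair_id": [f"P{i + 1}" for i in range(n)],
        "strain_a": panel_a.strains,
        "strain_b": panel_b.strains,
    })
    ca, cb = scenario.causal_indices()

    records = []
    rep_var = scenario.rep_noise_sd**2
    if scenario.treatment == "co":
        curves = co_mean_curves(scenario)
        stack = np.stack([curves[c] for c in quantgen.COMBO_ORDER])  # (4, 2T)
        if ca is None:
            mean_rows = np.tile(stack.mean(axis=0), (n, 1)) if scenario.h2 > 0 \
                else np.tile(curves["ab"], (n, 1))
            combo_idx = np.zeros(n, dtype=int)
        else:
            ga = panel_a.calls[:, ca]
            gb = panel_b.calls[:, cb]
            combo_names = np.array(["ab", "aB", "Ab", "AB"])
            combo_idx = 2 * ga + gb
            name_by_idx = {0: "ab", 1: "aB", 2: "Ab", 3: "AB"}
            mean_rows = np.stack([curves[name_by_idx[int(c)]] for c in combo_idx])
        # per-species residual scaling to hit the target heritability
        p = scenario.allele_freq
        freqs = np.array([p * p, p * (1 - p), (1 - p) * p, (1 - p) * (1 - p)])
        scales = np.ones(2)
        if scenario.h2 > 0:
            for k, sl in enumerate((slice(0, T), slice(T, 2 * T))):
                sub = stack[:, sl]
                ref = _reference_index(times, sub, scenario.ref_time)
                mbar = freqs @ sub[:, ref]
                vg = float(freqs @ (sub[:, ref] - mbar) ** 2)
                base_var = scenario.cov.var_a if k == 0 else scenario.cov.var_b
                scales[k] = _residual_scale(vg, scenario.h2, base_var, rep_var,
                                            scenario.n_replicates)
        cov = dc_replace(scenario.cov, var_a=scenario.cov.var_a * scales[0],
                         var_b=scenario.cov.var_b * scales[1])
        sigma = build_sigma(cov, times)
        L = np.linalg.cholesky(sigma)
        resid = rng.standard_normal((n, 2 * T)) @ L.T
        pair_log = mean_rows + resid
        rep_sd = scenario.rep_noise_sd * np.sqrt(scales)
        for i in range(n):
            for r in range(scenario.n_replicates):
                eps_a = rng.standard_normal(T) * rep_sd[0]
                eps_b = rng.standard_normal(T) * rep_sd[1]
                for sp, sl, strain, eps in (("A", slice(0, T), pairs.strain_a[i], eps_a),
                                            ("B", slice(T, 2 * T), pairs.strain_b[i], eps_b)):
                    vals = 10.0 ** (pair_log[i, sl] + eps)
                    for t_i, t in enumerate(times):
                        records.append((pairs.pair_id[i], sp, strain, "co", t,
                                        r + 1, vals[t_i]))
    else:  # monoculture
        curves = mono_mean_curves(scenario)
        scales = np.ones(2)
        if scenario.h2 > 0:
            for k, sp in enumerate(("a", "b")):
                sub = np.stack([curves[(sp, 0)], curves[(sp, 1)]])
                ref = _reference_index(times, sub, scenario.ref_time)
                pfreq = np.array([1 - scenario.allele_freq, scenario.allele_freq])
                mbar = pfreq @ sub[:, ref]
                vg = float(pfreq @ (sub[:, ref] - mbar) ** 2)
                base_var = scenario.cov.var_a if k == 0 else scenario.cov.var_b
                scales[k] = _residual_scale(vg, scenario.h2, base_var, rep_var,
                                            scenario.n_replicates)
        for k, (sp_tag, panel, strain_col, causal) in enumerate(
                (("A", panel_a, "strain_a", ca), ("B", panel_b, "strain_b", cb))):
            sp = "a" if k == 0 else "b"
            base_var = scenario.cov.var_a if k == 0 else scenario.cov.var_b
            cov_u = dc_replace(scenario.cov,
                               var_a=base_var * scales[k], var_b=1.0)
            sigma = build_sigma_univariate(cov_u, times, species="a") \
                if k == 0 else build_sigma_univariate(
                    dc_replace(scenario.cov, var_b=base_var * scales[k]), times, species="b")
            L = np.linalg.cholesky(sigma)
            geno = panel.calls[:, causal] if causal is not None else np.zeros(n, dtype=int)
            mean_rows = np.stack([curves[(sp, int(g))] for g in geno]) \
                if causal is not None else np.tile(curves[(sp, 0)], (n, 1))
            resid = rng.standard_normal((n, T)) @ L.T
            pair_log = mean_rows + resid
            rep_sd = scenario.rep_noise_sd * math.sqrt(scales[k])
            n0_sp = scenario.n0[k]
            for i in range(n):
                for r in range(scenario.n_replicates):
                    vals = n0_sp * 10.0 ** (pair_log[i] + rng.standard_normal(T) * rep_sd)
                    for t_i, t in enumerate(times):
                        records.append((pairs.pair_id[i], sp_tag,
                                        pairs[strain_col][i], "mono", t, r + 1,
                                        vals[t_i]))

    phen = pd.DataFrame.from_records(records, columns=PHENOTYPE_COLUMNS)
    meta = {"seed": seed, "treatment": scenario.treatment, "h2": scenario.h2,
            "causal_a": ca, "causal_b": cb, "n_replicates": scenario.n_replicates}
    return PairedCommunityDataset(panel_a=panel_a, panel_b=panel_b, pairs=pairs,
                                  phenotypes=phen, times=times, metadata=meta)


# ---------------------------------------------------------------------------
# power / false-positive-rate harness
# ---------------------------------------------------------------------------

def _run_method(method, ds: PairedCommunityDataset, scenario: SimScenario,
                n_perm: int, alpha: float, perm_seed: int):
    """One replicate: scan + genome-wide threshold; returns (result, threshold)."""
    times = scenario.times
    if method == "functional_mapping":
        treatment = scenario.treatment
        y = ds.abundance_matrix("a", treatment)
        panel = ds.panel_a
        geno_rows = ds.genotype_rows("a")
        panel = GenotypePanel(panel.markers, geno_rows, ds.strain_order("a"),
                              panel.species_tag)
        res = dynamic_mapping.functional_mapping_scan(panel, y, times)
    elif method == "cocom":
        if scenario.treatment != "co":
            raise ValueError("cocom requires co-culture data")
        pa = GenotypePanel(ds.panel_a.markers, ds.genotype_rows("a"),
                           ds.strain_order("a"), ds.panel_a.species_tag)
        pb = GenotypePanel(ds.panel_b.markers, ds.genotype_rows("b"),
                           ds.strain_order("b"), ds.panel_b.species_tag)
        res = dynamic_mapping.cocom_scan(pa, pb, ds.abundance_matrix("a", "co"),
                                         ds.abundance_matrix("b", "co"), times,
                                         n0=scenario.n0)
    else:
        raise ValueError(f"unknown method {method!r} (expected functional_mapping or cocom)")
    thr = dynamic_mapping.permutation_threshold(res.max_stat_fn, ds.n_pairs,
                                                n_perm=n_perm, alpha=alpha,
                                                seed=perm_seed)
    res.threshold = thr
    return res, thr


def estimate_power_fpr(
    scenario: SimScenario,
    method: str,
    n_reps: int = 50,
    seed: int = 0,
    n_perm: int = 50,
    alpha: float = 0.05,
) -> SimReport:
    """Monte-Carlo power and replicate-level false-positive rate of a method.

    Power: fraction of replicates in which the causal marker (pair) exceeds
    the genome-wide permutation threshold.  FPR (null scenarios): fraction
    of replicates in which any marker (pair) exceeds it.  For detected
    causal pairs of the cocom method, bias and RMSE of the interaction
    coefficients are reported.
    """
    if n_reps < 20:
        raise ValueError("need at least 20 replicates for a stable estimate")
    master = np.random.default_rng(seed)
    data_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    perm_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    ca, cb = scenario.causal_indices()
    is_null = ca is None
    hits = np.zeros(n_reps, dtype=bool)
    alpha_errs = []
    for rep in range(n_reps):
        ds = simulate_dataset(scenario, seed=int(data_seeds[rep]))
        res, thr = _run_method(method, ds, scenario, n_perm, alpha, int(perm_seeds[rep]))
        lrt = res.lrt
        if is_null:
            hits[rep] = bool(np.nanmax(lrt) > thr)
        elif method == "cocom":
            hits[rep] = bool(lrt[ca, cb] > thr)
            if hits[rep]:
                true = combo_lv_params(scenario)
                alphas = dynamic_mapping.profile_combo_alphas(
                    res, ds.abundance_matrix("a", "co"), ds.abundance_matrix("b", "co"),
                    ds.genotype_rows("a")[:, ca], ds.genotype_rows("b")[:, cb])
                for combo in quantgen.COMBO_ORDER:
                    a_es, a_se = alphas[combo]
                    if np.isfinite(a_es):
                        alpha_errs.append({
                            "combo": combo,
                            "err_alpha_es": a_es - true[combo].alpha_es,
                            "err_alpha_se": a_se - true[combo].alpha_se,
                        })
        else:
            hits[rep] = bool(lrt[ca] > thr)
    bias = None
    if alpha_errs:
        df = pd.DataFrame(alpha_errs)
        bias = df.groupby("combo").agg(["mean", lambda x: float(np.sqrt(np.mean(x**2)))])
        bias.columns = ["bias_alpha_es", "rmse_alpha_es", "bias_alpha_se", "rmse_alpha_se"]
    rate = float(hits.mean())
    return SimReport(
        method=method, treatment=scenario.treatment,
        power=None if is_null else rate, fpr=rate if is_null else None,
        n_replicates=n_reps, seed=seed, threshold_alpha=alpha,
        param_bias=bias, detections=hits,
    )
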