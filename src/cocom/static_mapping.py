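"""Time-point-wise (static) QTL mapping.

Monoculture abundance at one time is mapped per species by a univariate
two-group Gaussian likelihood-ratio test at each marker.  Co-culture
abundance is mapped by a four-component bivariate-normal mixture over the
interspecific genotype combinations of one marker pair: component means are
combo-specific, the 2x2 covariance (species variances plus a species-species
correlation) is shared, and each strain pair's component weights are the
conditional probabilities of its QTL combo given its marker combo
(one-hot "marker-as-QTL" weights by default).

Marker filtering (minor-allele frequency, missingness) runs before any scan;
chi-square p-values are descriptive only, genome-wide significance comes
from permutation thresholds shared with the dynamic module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "MixtureWeights",
    "StaticScanResult",
    "filter_markers",
    "adjust_structure",
    "em_bivariate_mixture",
    "static_scan",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GenotypePanel:
    """Haploid biallelic marker panel for one species' strain panel.

    ``calls`` is (n_strains, n_markers) int8 with values {0, 1} and -1 for
    missing; ``markers`` is a DataFrame with columns marker_id, pos;
    ``strains`` the strain identifiers in row order.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    strains: list
    species_tag: str = ""

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a strains x markers matrix")
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise ValueError("calls shape must match strains x markers")
        bad = ~np.isin(self.calls, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1 or -1 (missing)")
        if "pos" in self.markers and (np.asarray(self.markers["pos"]) < 0).any():
            raise ValueError("marker positions must be nonnegative")

    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.markers.iloc[keep].reset_index(drop=True),
                             self.calls[:, keep], self.strains, self.species_tag)


@dataclass
class MixtureWeights:
    """Per-pair conditional probabilities of the four QTL genotype combos.

    ``w`` is (n_pairs, 4) in combo order (AB, Ab, aB, ab); rows are
    nonnegative and sum to one.  Rows of a pair with missing genotype data
    may be all-NaN, which drops the pair from the likelihood.
    """

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 4:
            raise ValueError("weights must be (n_pairs, 4)")
        valid = ~np.any(np.isnan(self.w), axis=1)
        if np.any(self.w[valid] < -1e-12):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.w[valid].sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("weight rows must sum to 1")

    @classmethod
    def one_hot(cls, geno_a: np.ndarray, geno_b: np.ndarray) -> "MixtureWeights":
        """Marker-as-QTL weights from the observed marker genotypes (1=upper)."""
        n = len(geno_a)
        w = np.full((n, 4), np.nan)
        combo_idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
        for i in range(n):
            ga, gb = int(geno_a[i]), int(geno_b[i])
            if ga >= 0 and gb >= 0:
                w[i] = 0.0
                w[i, combo_idx[(ga, gb)]] = 1.0
        return cls(w)


@dataclass
class StaticScanResult:
    """Tidy per-test results of a static scan."""

    table: pd.DataFrame
    treatment: str
    times: np.ndarray


def filter_markers(panel: GenotypePanel, maf_min: float = 0.1,
                   missing_max: float = 0.2) -> tuple[GenotypePanel, np.ndarray]:
    """Apply MAF and missingness filters; returns (filtered panel, kept indices)."""
    calls = panel.calls
    n = calls.shape[0]
    miss = np.mean(calls < 0, axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n - (calls < 0).sum(0) > 0,
                        np.sum(np.where(calls < 0, 0, calls), axis=0)
                        / np.maximum(n - (calls < 0).sum(0), 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.nonzero((miss <= missing_max) & (maf >= maf_min))[0]
    return panel.subset(keep), keep


def adjust_structure(phenotypes, subpop_labels) -> np.ndarray:
    """Remove subpopulation (population-structure) mean differences.

    Per column (time point), phenotypes are replaced by the residual of a
    regression on subpopulation indicators, recentred on the grand mean --
    equivalently, group-mean centering.  Subpopulations with fewer than two
    strains are merged into a single pooled group with a warning.
    """
    y = np.asarray(phenotypes, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y.T).T if squeeze else y
    labels = np.asarray(subpop_labels)
    if len(labels) != y.shape[0]:
        raise ValueError("one subpopulation label per strain is required")
    labels = labels.astype(object).copy()
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if len(small):
        warnings.warn(f"merging subpopulations with <2 strains: {list(small)}",
                      stacklevel=2)
        labels[np.isin(labels, small)] = "__merged__"
    out = y.copy()
    grand = y.mean(axis=0)
    for g in np.unique(labels):
        rows = labels == g
        out[rows] = y[rows] - y[rows].mean(axis=0) + grand
    return out[:, 0] if squeeze else out


def _bivar_logpdf(y, mean, cov):
    """Log density of bivariate normal for rows of y (n, 2)."""
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 0:
        return np.full(len(y), -np.inf)
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
    d = y - mean
    q = np.einsum("ni,ij,nj->n", d, inv, d)
    return -0.5 * (q + np.log(det)) - _LOG2PI


def em_bivariate_mixture(
    y_a: np.ndarray,
    y_b: np.ndarray,
    weights: MixtureWeights,
    max_iter: int = 500,
    tol: float = 1e-8,
    var_floor_frac: float = 1e-8,
):
    """EM for the four-component bivariate-normal mixture at one time point.

    Components share one 2x2 covariance (sigma_A^2, sigma_B^2, rho); the
    fixed per-pair weights are the prior combo probabilities.  The
    log-likelihood is non-decreasing across iterations; convergence is a
    relative change below ``tol``.  Returns a dict with combo ``means``
    (4, 2), ``sigma2_a``, ``sigma2_b``, ``rho``, ``loglik``, ``n_iter``,
    ``responsibilities`` and a ``floored`` flag.
    """
    y = np.column_stack([np.asarray(y_a, float), np.asarray(y_b, float)])
    w = weights.w
    valid = ~np.any(np.isnan(w), axis=1) & ~np.any(np.isnan(y), axis=1)
    y, w = y[valid], w[valid]
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 informative strain pairs")
    floor = var_floor_frac * np.maximum(y.var(axis=0), 1e-300)

    # init: overall mean plus small combo offsets ordered by weight
    mu = np.tile(y.mean(axis=0), (4, 1)) + 1e-3 * np.arange(4)[:, None] * y.std(axis=0)
    cov = np.cov(y.T) + np.diag(floor)
    loglik = -np.inf
    floored = False
    resp = None
    path = []
    for it in range(1, max_iter + 1):
        logp = np.stack([_bivar_logpdf(y, mu[c], cov) for c in range(4)], axis=1)
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf)
        joint = logw + logp
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        new_loglik = float(lse.sum())
        path.append(new_loglik)
        resp = np.exp(joint - lse[:, None])
        # M step
        tot = resp.sum(axis=0)
        for c in range(4):
            if tot[c] > 1e-12:
                mu[c] = resp[:, c] @ y / tot[c]
        d = y[:, None, :] - mu[None, :, :]
        cov = np.einsum("nc,nci,ncj->ij", resp, d, d) / n
        if cov[0, 0] < floor[0] or cov[1, 1] < floor[1]:
            cov[0, 0] = max(cov[0, 0], floor[0])
            cov[1, 1] = max(cov[1, 1], floor[1])
            floored = True
        # keep correlation valid
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        if abs(r) > 0.999:
            cov[0, 1] = cov[1, 0] = np.sign(r) * 0.999 * np.sqrt(cov[0, 0] * cov[1, 1])
        if new_loglik - loglik < tol * (abs(loglik) + 1e-12) and it > 1:
            loglik = new_loglik
            break
        loglik = new_loglik
    rho = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    return {
        "means": mu,
        "sigma2_a": float(cov[0, 0]),
        "sigma2_b": float(cov[1, 1]),
        "rho": rho,
        "loglik": loglik,
        "n_iter": it,
        "loglik_path": np.asarray(path),
        "responsibilities": resp,
        "floored": floored,
    }


def _gauss_loglik_rows(y: np.ndarray) -> float:
    """Max bivariate-Gaussian loglik of rows with free mean/cov (ML)."""
    n = len(y)
    mu = y.mean(axis=0)
    d = y - mu
    cov = d.T @ d / n
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    det = max(det, 1e-300)
    return -0.5 * n * (np.log(det) + 2.0) - n * _LOG2PI


def _grouped_loglik(y: np.ndarray, groups: np.ndarray) -> float:
    """Max loglik with free combo means, shared ML covariance."""
    n = len(y)
    d = y.copy()
    for g in np.unique(groups):
        rows = groups == g
        d[rows] -= y[rows].mean(axis=0)
    cov = d.T @ d / n
    det = max(cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2, 1e-300)
    return -0.5 * n * (np.log(det) + 2.0) - n * _LOG2PI


def static_scan(
    panel_a: GenotypePanel,
    panel_b: GenotypePanel | None,
    abundance_a: np.ndarray,
    abundance_b: np.ndarray | None,
    times,
    treatment: str = "co",
    maf_min: float = 0.1,
    missing_max: float = 0.2,
) -> StaticScanResult:
    """Marker(-pair) x time LRT scan of single-time abundances.

    ``abundance_a``/``abundance_b`` are (n, T) per-strain(-pair) matrices
    aligned with panel rows.  For co-culture both panels and phenotypes are
    required and each marker pair is tested with the four-combo bivariate
    model (one-hot weights); monoculture tests each species separately with
    the univariate two-group model.  Returns tidy results with the LRT and
    fitted moments per test.
    """
    times = np.asarray(times, dtype=float)
    ya = np.asarray(abundance_a, dtype=float)
    panel_a, _ = filter_markers(panel_a, maf_min, missing_max)
    records = []
    if treatment == "mono":
        panels = [("A", panel_a, ya)]
        if panel_b is not None:
            panel_b, _ = filter_markers(panel_b, maf_min, missing_max)
            panels.append(("B", panel_b, np.asarray(abundance_b, float)))
        for tag, panel, y in panels:
            for j in range(panel.n_markers):
                g = panel.calls[:, j]
                ok = g >= 0
                if len(np.unique(g[ok])) < 2:
                    continue  # monomorphic after missing-drop
                for ti, t in enumerate(times):
                    yy = y[ok, ti]
                    gg = g[ok]
                    n = len(yy)
                    v0 = yy.var()
                    d = yy.copy()
                    m0 = yy[gg == 0].mean()
                    m1 = yy[gg == 1].mean()
                    d[gg == 0] -= m0
                    d[gg == 1] -= m1
                    v1 = max((d**2).mean(), 1e-300)
                    lrt = n * np.log(max(v0, 1e-300) / v1)
                    records.append({"species": tag, "marker": panel.markers.iloc[j]["marker_id"],
                                    "time_h": t, "lrt": max(lrt, 0.0),
                                    "mean_0": m0, "mean_1": m1, "sigma2": v1})
    elif treatment == "co":
        if panel_b is None or abundance_b is None:
            raise ValueError("co-culture scan requires both panels and phenotypes")
        yb = np.asarray(abundance_b, dtype=float)
        panel_b, _ = filter_markers(panel_b, maf_min, missing_max)
        for ja in range(panel_a.n_markers):
            ga = panel_a.calls[:, ja]
            for jb in range(panel_b.n_markers):
                gb = panel_b.calls[:, jb]
                ok = (ga >= 0) & (gb >= 0)
                groups = 2 * ga[ok] + gb[ok]
                if len(np.unique(groups)) < 2:
                    continue
                for ti, t in enumerate(times):
                    y = np.column_stack([ya[ok, ti], yb[ok, ti]])
                    l1 = _grouped_loglik(y, groups)
                    l0 = _gauss_loglik_rows(y)
                    means = np.full((4, 2), np.nan)
                    for c in np.unique(groups):
                        means[int(c)] = y[groups == c].mean(axis=0)
                    records.append({
                        "marker_a": panel_a.markers.iloc[ja]["marker_id"],
                        "marker_b": panel_b.markers.iloc[jb]["marker_id"],
                        "time_h": t, "lrt": max(2.0 * (l1 - l0), 0.0),
                        "mean_AB_a": means[3, 0], "mean_AB_b": means[3, 1],
                        "mean_Ab_a": means[2, 0], "mean_Ab_b": means[2, 1],
                        "mean_aB_a": means[1, 0], "mean_aB_b": means[1, 1],
                        "mean_ab_a": means[0, 0], "mean_ab_b": means[0, 1],
                    })
    else:
        raise ValueError("treatment must be 'mono' or 'co'")
    return StaticScanResult(table=pd.DataFrame.from_records(records),
                            treatment=treatment, times=times)
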