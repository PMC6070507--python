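"""Decomposition of interspecific genotype-combination values into direct,
indirect, and genome-genome epistatic genetic effects.

Two haploid QTLs, one per species (alleles A/a in species A, B/b in species
B), form four genotype combinations AB, Ab, aB, ab.  For each affected
species l the four genotypic-value curves mu^l_AB(t), ..., mu^l_ab(t)
decompose into a population mean, a direct effect of the species' own QTL,
an indirect effect of the partner species' QTL, and a genome-genome
epistatic effect.  With +/-1 contrast codes x_A, x_B for the two loci,

    mu^l_c(t) = mu^l(t) + a_own x_own + a_partner x_partner + I x_A x_B,

so the effects are quarter contrasts of the four combo values and the map is
an exact linear bijection.  Variance components under combo frequencies
follow, along with per-QTL-pair and multi-locus heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ComboValues",
    "GeneticEffects",
    "VarianceComponents",
    "COMBO_ORDER",
    "decompose_effects",
    "compose_effects",
    "variance_components",
    "multi_locus_heritability",
]

#: Canonical ordering of the four interspecific genotype combinations.
COMBO_ORDER = ("AB", "Ab", "aB", "ab")

# contrast codes per combo: (x_A, x_B) with uppercase allele = +1
_CODES = {"AB": (1, 1), "Ab": (1, -1), "aB": (-1, 1), "ab": (-1, -1)}


def _as_grid(curves) -> np.ndarray:
    arr = np.asarray(curves, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :].T if False else arr  # scalar-per-time 1-D grid accepted
    if not np.all(np.isfinite(arr)):
        raise ValueError("curves must be finite")
    return arr


@dataclass
class ComboValues:
    """Genotypic-value curves of the four combos for both affected species.

    ``species_a``/``species_b`` are (4, T) arrays in :data:`COMBO_ORDER`
    (row order AB, Ab, aB, ab), giving the value of species A's and species
    B's phenotype respectively.  T may be 1 for a static (single time) value.
    """

    species_a: np.ndarray
    species_b: np.ndarray

    def __post_init__(self):
        self.species_a = np.atleast_2d(np.asarray(self.species_a, dtype=float))
        self.species_b = np.atleast_2d(np.asarray(self.species_b, dtype=float))
        for arr in (self.species_a, self.species_b):
            if arr.shape[0] != 4:
                raise ValueError("expected four combo curves (AB, Ab, aB, ab)")
            if not np.all(np.isfinite(arr)):
                raise ValueError("combo values must be finite")
        if self.species_a.shape[1] != self.species_b.shape[1]:
            raise ValueError("both species' curves must share one time grid")


@dataclass
class GeneticEffects:
    """Time-indexed genetic-effect curves for one QTL pair.

    mu_a/mu_b: population means of each species' phenotype;
    direct_a (a_A^A): species A's QTL on its own phenotype;
    direct_b (a_B^B): species B's QTL on its own phenotype;
    indirect_a_on_b (a_A^B): species A's QTL on species B's phenotype;
    indirect_b_on_a (a_B^A): species B's QTL on species A's phenotype;
    epi_a, epi_b (I^A, I^B): genome-genome epistasis on each species.
    """

    mu_a: np.ndarray
    mu_b: np.ndarray
    direct_a: np.ndarray
    direct_b: np.ndarray
    indirect_a_on_b: np.ndarray
    indirect_b_on_a: np.ndarray
    epi_a: np.ndarray
    epi_b: np.ndarray

    def __post_init__(self):
        arrs = [np.atleast_1d(np.asarray(getattr(self, f), dtype=float))
                for f in ("mu_a", "mu_b", "direct_a", "direct_b",
                          "indirect_a_on_b", "indirect_b_on_a", "epi_a", "epi_b")]
        T = arrs[0].shape[0]
        if any(a.shape != (T,) for a in arrs):
            raise ValueError("all eight effect curves must share one time grid")
        (self.mu_a, self.mu_b, self.direct_a, self.direct_b,
         self.indirect_a_on_b, self.indirect_b_on_a, self.epi_a, self.epi_b) = arrs


@dataclass
class VarianceComponents:
    """Per-species genetic variance components at each time point.

    Arrays are (T,): direct/indirect/epistatic variances, their proportions
    of total genetic variance, the total genetic variance, and heritability
    h2 = V_genetic / V_phenotypic.
    """

    direct: np.ndarray
    indirect: np.ndarray
    epistatic: np.ndarray
    prop_direct: np.ndarray
    prop_indirect: np.ndarray
    prop_epistatic: np.ndarray
    total_genetic: np.ndarray
    h2: np.ndarray
    pheno_var: np.ndarray = field(default=None)


def decompose_effects(combos: ComboValues) -> GeneticEffects:
    """Solve the quarter-contrast formulas per time point.

    For the phenotype of species A (and symmetrically for B):
      mean      mu^A  = (mu_AB + mu_Ab + mu_aB + mu_ab) / 4
      direct    a_A^A = (mu_AB + mu_Ab - mu_aB - mu_ab) / 4
      indirect  a_B^A = (mu_AB - mu_Ab + mu_aB - mu_ab) / 4
      epistasis I^A   = (mu_AB - mu_Ab - mu_aB + mu_ab) / 4
    """
    ya, yb = combos.species_a, combos.species_b
    ab, Ab_, aB_, ab_low = 0, 1, 2, 3  # indices in COMBO_ORDER

    def contrasts(y):
        mean = 0.25 * (y[0] + y[1] + y[2] + y[3])
        own_a = 0.25 * (y[0] + y[1] - y[2] - y[3])   # species-A locus contrast
        own_b = 0.25 * (y[0] - y[1] + y[2] - y[3])   # species-B locus contrast
        epi = 0.25 * (y[0] - y[1] - y[2] + y[3])
        return mean, own_a, own_b, epi

    mu_a, aAA, aBA, epi_a = contrasts(ya)
    mu_b, aAB, aBB, epi_b = contrasts(yb)
    return GeneticEffects(
        mu_a=mu_a, mu_b=mu_b,
        direct_a=aAA, direct_b=aBB,
        indirect_a_on_b=aAB, indirect_b_on_a=aBA,
        epi_a=epi_a, epi_b=epi_b,
    )


def compose_effects(effects: GeneticEffects) -> ComboValues:
    """Rebuild the four combo-value curves; exact inverse of decompose_effects."""
    rows_a, rows_b = [], []
    for combo in COMBO_ORDER:
        xa, xb = _CODES[combo]
        rows_a.append(effects.mu_a + xa * effects.direct_a
                      + xb * effects.indirect_b_on_a + xa * xb * effects.epi_a)
        rows_b.append(effects.mu_b + xa * effects.indirect_a_on_b
                      + xb * effects.direct_b + xa * xb * effects.epi_b)
    return ComboValues(species_a=np.stack(rows_a), species_b=np.stack(rows_b))


def _component_variances(own, partner, epi, freqs):
    """Frequency-weighted variances of the three contrast components.

    Each component contributes coef(t) * code_c; its variance under combo
    frequencies p_c is coef^2 * Var_p(code).  Codes are +/-1 so the variance
    of each code column is 1 - (sum_c p_c code_c)^2.
    """
    codes = np.array([_CODES[c] for c in COMBO_ORDER], dtype=float)  # (4, 2)
    xa, xb = codes[:, 0], codes[:, 1]
    xab = xa * xb
    va_code = 1.0 - float(freqs @ xa) ** 2
    vb_code = 1.0 - float(freqs @ xb) ** 2
    vab_code = 1.0 - float(freqs @ xab) ** 2
    return own**2 * va_code, partner**2 * vb_code, epi**2 * vab_code


def variance_components(
    effects: GeneticEffects,
    species: str,
    pheno_var,
    combo_freqs: Sequence[float] | None = None,
) -> VarianceComponents:
    """Genetic variance components and heritability for one affected species.

    Under equal combo frequencies the three contrasts are orthogonal and each
    component's variance is simply the squared effect, summing exactly to the
    variance of the four combo means.  Under observed frequencies each
    component's variance is the frequency-weighted dispersion it induces
    (coef^2 times the code variance); the components are then correlated, so
    the total genetic variance is the frequency-weighted variance of the
    combo means and the three shares are normalized to sum to one.

    ``species`` selects the affected phenotype ('a' or 'b').
    """
    if species not in ("a", "b"):
        raise ValueError("species must be 'a' or 'b'")
    if combo_freqs is None:
        freqs = np.full(4, 0.25)
    else:
        freqs = np.asarray(combo_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("combo_freqs must be four nonnegative values summing to 1")
    pheno_var = np.broadcast_to(np.asarray(pheno_var, dtype=float), effects.mu_a.shape).copy()
    if np.any(pheno_var <= 0):
        raise ValueError("phenotypic variance must be positive")

    if species == "a":
        own, partner, epi = effects.direct_a, effects.indirect_b_on_a, effects.epi_a
        combo_vals = compose_effects(effects).species_a
    else:
        own, partner, epi = effects.direct_b, effects.indirect_a_on_b, effects.epi_b
        combo_vals = compose_effects(effects).species_b

    v_dir, v_ind, v_epi = _component_variances(own, partner, epi, freqs)
    wmean = freqs @ combo_vals
    total = freqs @ (combo_vals - wmean) ** 2
    comp_sum = v_dir + v_ind + v_epi
    # proportions are normalized component shares; under equal frequencies the
    # contrasts are orthogonal, comp_sum == total, and the rescale is exactly 1
    safe = np.where(comp_sum > 0, comp_sum, 1.0)
    props = np.stack([v_dir, v_ind, v_epi]) / safe
    props[:, comp_sum <= 0] = 0.0
    scale = np.where(comp_sum > 0, total / safe, 0.0)
    h2 = np.minimum(total / pheno_var, 1.0)
    return VarianceComponents(
        direct=v_dir * scale,
        indirect=v_ind * scale,
        epistatic=v_epi * scale,
        prop_direct=props[0],
        prop_indirect=props[1],
        prop_epistatic=props[2],
        total_genetic=total,
        h2=h2,
        pheno_var=pheno_var,
    )


def multi_locus_heritability(per_pair_components: Sequence[VarianceComponents]):
    """Summed heritability over significant QTL pairs for one species.

    Adds per-pair total genetic variances against the shared phenotypic
    variance (no linkage-disequilibrium correction, so an upper bound under
    linkage equilibrium).  Returns (h2_total (T,), aggregate indirect+epistatic
    share (T,)).
    """
    comps = list(per_pair_components)
    if not comps:
        raise ValueError("no variance components supplied")
    pv0 = comps[0].pheno_var
    for c in comps[1:]:
        if not np.allclose(c.pheno_var, pv0, rtol=1e-10):
            raise ValueError("all pairs must be computed against a shared phenotypic variance")
    total_g = np.sum([c.total_genetic for c in comps], axis=0)
    nondirect = np.sum([c.indirect + c.epistatic for c in comps], axis=0)
    h2 = total_g / pv0
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total_g > 0, nondirect / np.where(total_g > 0, total_g, 1.0), 0.0)
    return h2, share
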