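"""The paired-community dataset container.

Holds the genotype panels of both species, the strain pairing, and the
mono- and co-culture abundance trajectories in long format, with
replicate-averaged accessors used by the mapping modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .static_mapping import GenotypePanel

__all__ = ["PairedCommunityDataset", "PHENOTYPE_COLUMNS"]

PHENOTYPE_COLUMNS = ["pair_id", "species", "strain_id", "treatment",
                     "time_h", "replicate", "abundance"]


@dataclass
class PairedCommunityDataset:
    """Genotypes, pairing and abundance trajectories of n interspecific pairs.

    ``pairs`` has columns pair_id, strain_a, strain_b; each strain belongs
    to exactly one pair (independent-pairs design).  ``phenotypes`` is the
    long-format table with columns :data:`PHENOTYPE_COLUMNS`; abundances are
    copies/mL.  Raw replicates are retained; the mapping modules consume the
    replicate-averaged matrices from :meth:`abundance_matrix`.
    """

    panel_a: GenotypePanel
    panel_b: GenotypePanel
    pairs: pd.DataFrame
    phenotypes: pd.DataFrame
    times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.phenotypes.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        for col in ("strain_a", "strain_b"):
            dup = self.pairs[col][self.pairs[col].duplicated()]
            if len(dup):
                raise ValueError(
                    f"strain {dup.iloc[0]!r} appears in multiple pairs; the design "
                    "requires independent pairs (each strain in at most one pair)"
                )
        known_a = set(self.panel_a.strains)
        known_b = set(self.panel_b.strains)
        bad_a = set(self.pairs["strain_a"]) - known_a
        bad_b = set(self.pairs["strain_b"]) - known_b
        if bad_a or bad_b:
            raise ValueError(f"pairing references unknown strains: {sorted(bad_a | bad_b)}")
        extra_t = set(np.round(self.phenotypes["time_h"].astype(float), 9)) \
            - set(np.round(self.times, 9))
        if extra_t:
            raise ValueError(f"phenotype times {sorted(extra_t)} not in metadata times")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def strain_order(self, species: str) -> list:
        col = "strain_a" if species == "a" else "strain_b"
        return list(self.pairs[col])

    def abundance_matrix(self, species: str, treatment: str) -> np.ndarray:
        """(n_pairs, T) replicate-averaged abundances aligned with pair order."""
        tag = {"a": "A", "b": "B"}[species]
        sub = self.phenotypes[(self.phenotypes["species"] == tag)
                              & (self.phenotypes["treatment"] == treatment)]
        if sub.empty:
            raise ValueError(f"no phenotypes for species {tag!r}, treatment {treatment!r}")
        avg = (sub.groupby(["pair_id", "time_h"], sort=True)["abundance"]
               .mean().unstack("time_h"))
        avg = avg.reindex(index=self.pairs["pair_id"], columns=np.sort(self.times))
        if avg.isna().any().any():
            raise ValueError("incomplete trajectories after replicate averaging")
        return avg.to_numpy()

    def genotype_rows(self, species: str) -> np.ndarray:
        """Genotype calls reordered to pair order (one row per pair)."""
        panel = self.panel_a if species == "a" else self.panel_b
        order = self.strain_order(species)
        idx = [panel.strains.index(s) for s in order]
        return panel.calls[idx]
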