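"""File readers and writers.

Formats:
  * Genotypes: a TSV dialect (columns marker_id, pos, then one haploid
    single-character allele call per strain; "." = missing) or VCF with
    haploid GT fields (read via cyvcf2 when available).  Positions are
    1-based in all I/O.
  * Phenotypes: long-format CSV with header pair_id,species,strain_id,
    treatment,time_h,replicate,abundance (copies/mL).
  * Pairing: CSV with header pair_id,strain_a,strain_b.

Readers validate rather than coerce: errors name the file, the line and the
violated rule.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PairedCommunityDataset, PHENOTYPE_COLUMNS
from .static_mapping import GenotypePanel

__all__ = [
    "read_genotypes_tsv", "write_genotypes_tsv", "read_genotypes_vcf",
    "read_phenotypes", "write_phenotypes", "read_pairing", "write_pairing",
    "read_dataset", "write_dataset", "write_fitted_curves", "write_effects",
]


class FormatError(ValueError):
    """Malformed input file; message names file, line and rule."""


def _err(path, line, msg):
    raise FormatError(f"{path}:{line}: {msg}")


def read_genotypes_tsv(path, species_tag: str = "") -> GenotypePanel:
    """Read the TSV genotype dialect into a GenotypePanel.

    Allele coding: per marker, the alphabetically first observed allele
    character maps to 0 and the second to 1; "." is missing.  More than two
    alleles is an error (markers must be biallelic).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["marker_id", "pos"]:
            _err(path, 1, "header must start with 'marker_id\\tpos'")
        strains = header[2:]
        if not strains:
            _err(path, 1, "no strain columns")
        marker_ids, positions, rows = [], [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                _err(path, ln, f"expected {len(header)} fields, got {len(parts)}")
            try:
                pos = int(parts[1])
            except ValueError:
                _err(path, ln, f"position {parts[1]!r} is not an integer")
            if pos < 1:
                _err(path, ln, "positions are 1-based and must be >= 1")
            alleles = sorted({a for a in parts[2:] if a != "."})
            if len(alleles) > 2:
                _err(path, ln, f"marker {parts[0]} has >2 alleles: {alleles}")
            code = {a: i for i, a in enumerate(alleles)}
            code["."] = -1
            rows.append([code[a] for a in parts[2:]])
            marker_ids.append(parts[0])
            positions.append(pos)
    markers = pd.DataFrame({"marker_id": marker_ids, "pos": positions})
    calls = np.asarray(rows, dtype=np.int8).T  # strains x markers
    return GenotypePanel(markers, calls, strains, species_tag=species_tag)


def write_genotypes_tsv(panel: GenotypePanel, path, alleles=("A", "C")) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("marker_id\tpos\t" + "\t".join(map(str, panel.strains)) + "\n")
        for j in range(panel.n_markers):
            row = panel.markers.iloc[j]
            calls = ["." if c < 0 else alleles[c] for c in panel.calls[:, j]]
            fh.write(f"{row['marker_id']}\t{int(row['pos'])}\t" + "\t".join(calls) + "\n")


def read_genotypes_vcf(path, species_tag: str = "") -> GenotypePanel:
    """Read haploid GT calls from a VCF into a GenotypePanel."""
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from err
    path = str(path)
    vcf = VCF(path)
    strains = list(vcf.samples)
    marker_ids, positions, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"{path}: marker {var.ID or var.POS} is not biallelic")
        gt = np.asarray(var.gt_types)
        # cyvcf2 encodes haploid calls as HOM_REF(0)/HOM_ALT(3); UNKNOWN(2)
        row = np.where(gt == 0, 0, np.where(gt == 3, 1, -1)).astype(np.int8)
        rows.append(row)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
    markers = pd.DataFrame({"marker_id": marker_ids, "pos": positions})
    return GenotypePanel(markers, np.asarray(rows, dtype=np.int8).T, strains,
                         species_tag=species_tag)


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: phenotype header lacks columns {missing}")
    ab = pd.to_numeric(df["abundance"], errors="coerce")
    if ab.isna().any():
        ln = int(df.index[ab.isna()][0]) + 2
        raise FormatError(f"{path}:{ln}: non-numeric abundance value")
    if (ab < 0).any():
        ln = int(df.index[ab < 0][0]) + 2
        raise FormatError(f"{path}:{ln}: negative abundance")
    df["abundance"] = ab
    df["time_h"] = pd.to_numeric(df["time_h"])
    key = ["pair_id", "species", "treatment", "replicate"]
    monotone = df.groupby(key, sort=False)["time_h"] \
        .apply(lambda s: s.is_monotonic_increasing)
    if not monotone.all():
        warnings.warn(f"{path}: times were not sorted within trajectories; sorting",
                      stacklevel=2)
        df = df.sort_values(key + ["time_h"], ignore_index=True, kind="stable")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


def read_pairing(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    need = ["pair_id", "strain_a", "strain_b"]
    if list(df.columns[:3]) != need:
        raise FormatError(f"{path}:1: pairing header must be {','.join(need)}")
    for col in ("strain_a", "strain_b"):
        dup = df[col][df[col].duplicated()]
        if len(dup):
            ln = int(dup.index[0]) + 2
            raise FormatError(
                f"{path}:{ln}: strain {dup.iloc[0]!r} is paired more than once; "
                "the design requires independent pairs")
    return df


def write_pairing(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["pair_id", "strain_a", "strain_b"])


def _read_genotypes_any(path, species_tag):
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path, species_tag=species_tag)
    return read_genotypes_tsv(path, species_tag=species_tag)


def read_dataset(genotype_a_path, genotype_b_path, phenotype_path,
                 pairing_path, times=None) -> PairedCommunityDataset:
    """Assemble and validate a PairedCommunityDataset from its four files.

    Genotype files may be the TSV dialect or VCF (by extension)."""
    panel_a = _read_genotypes_any(genotype_a_path, species_tag="A")
    panel_b = _read_genotypes_any(genotype_b_path, species_tag="B")
    phen = read_phenotypes(phenotype_path)
    pairs = read_pairing(pairing_path)
    if times is None:
        times = np.sort(phen["time_h"].unique())
    return PairedCommunityDataset(panel_a=panel_a, panel_b=panel_b, pairs=pairs,
                                  phenotypes=phen, times=np.asarray(times, float))


def write_dataset(ds: PairedCommunityDataset, outdir) -> dict:
    """Write the four dataset files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_a": outdir / "genotypes_a.tsv",
        "genotypes_b": outdir / "genotypes_b.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "pairing": outdir / "pairing.csv",
    }
    write_genotypes_tsv(ds.panel_a, paths["genotypes_a"])
    write_genotypes_tsv(ds.panel_b, paths["genotypes_b"])
    write_phenotypes(ds.phenotypes, paths["phenotypes"])
    write_pairing(ds.pairs, paths["pairing"])
    return paths


def write_fitted_curves(fits, path) -> None:
    """Tidy CSV of fitted growth-model parameters: entity, model, parameter, estimate."""
    rows = []
    for entity, params in fits:
        model = getattr(params, "model_id", "lotka_volterra")
        if hasattr(params, "A"):
            items = [("A", params.A), ("r", params.r), ("lam", params.lam)]
            if params.v is not None:
                items.append(("v", params.v))
        else:
            items = [("r_e", params.r_e), ("K_e", params.K_e),
                     ("alpha_es", params.alpha_es), ("r_s", params.r_s),
                     ("K_s", params.K_s), ("alpha_se", params.alpha_se)]
        for name, val in items:
            rows.append({"entity": entity, "model": model,
                         "parameter": name, "estimate": val})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_effects(qtl_pair: str, effects, times, path, variance=None) -> None:
    """Tidy CSV of effect curves: qtl_pair, species, time_h, effect_type, estimate."""
    rows = []
    curves = {
        ("A", "direct"): effects.direct_a, ("B", "direct"): effects.direct_b,
        ("B", "indirect"): effects.indirect_a_on_b,
        ("A", "indirect"): effects.indirect_b_on_a,
        ("A", "epistasis"): effects.epi_a, ("B", "epistasis"): effects.epi_b,
    }
    for (sp, kind), curve in curves.items():
        for t, val in zip(np.atleast_1d(times), np.atleast_1d(curve)):
            rows.append({"qtl_pair": qtl_pair, "species": sp, "time_h": t,
                         "effect_type": kind, "estimate": val})
    pd.DataFrame(rows).to_csv(path, index=False)
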