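"""Text interchange: PLINK-raw-style dosages, phenotype/pedigree CSV, locus map.

The genotype format follows PLINK's ``--recode A`` layout: a whitespace-
delimited header ``FID IID PAT MAT SEX PHENOTYPE snp...`` and one row per
individual with allele dosages 0/1/2.  Readers accept the minimal variant
(``FID IID`` + dosage columns) as well.  VCF input is supported when cyvcf2
is installed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import SimResult

__all__ = [
    "write_plink_raw",
    "read_plink_raw",
    "write_locus_map",
    "read_locus_map",
    "write_pedigree",
    "read_pedigree",
    "read_vcf",
    "export",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(
    path: str | Path,
    dosages: np.ndarray,
    ids: np.ndarray,
    snp_names: list[str] | None = None,
) -> None:
    if snp_names is None:
        snp_names = [f"snp{i}" for i in range(dosages.shape[1])]
    if len(snp_names) != dosages.shape[1]:
        raise ValueError("snp_names length does not match dosage columns")
    df = pd.DataFrame(dosages, columns=snp_names)
    df.insert(0, "PHENOTYPE", -9)
    df.insert(0, "SEX", 0)
    df.insert(0, "MAT", 0)
    df.insert(0, "PAT", 0)
    df.insert(0, "IID", ids)
    df.insert(0, "FID", ids)
    df.to_csv(path, sep=" ", index=False)


def read_plink_raw(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (dosages int8, ids, snp column names)."""
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except OSError as e:
        raise OSError(f"cannot read genotype file {path}: {e}") from e
    meta = [c for c in _RAW_META if c in df.columns]
    if "IID" not in meta:
        raise ValueError(f"{path}: not a PLINK-raw-style file (no IID column)")
    snp_cols = [c for c in df.columns if c not in _RAW_META]
    dos = df[snp_cols].to_numpy()
    if not np.isin(dos, (0, 1, 2)).all():
        raise ValueError(f"{path}: dosages outside {{0,1,2}}")
    return dos.astype(np.int8), df["IID"].to_numpy(), snp_cols


def write_locus_map(path: str | Path, locus_map: pd.DataFrame) -> None:
    locus_map.to_csv(path, index=False)


def read_locus_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"chrom", "pos_cM", "is_qtl"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: locus map missing columns {sorted(missing)}")
    return df


def write_pedigree(path: str | Path, pedigree: pd.DataFrame) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs 'id' and 'phenotype' columns")
    return df


def read_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Dosages, sample ids and a locus map from a VCF (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples)
    rows, chroms, pos = [], [], []
    for variant in vcf:
        gt = np.asarray(variant.gt_types)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        if (dos < 0).any():
            raise ValueError(f"missing genotypes at {variant.CHROM}:{variant.POS}")
        rows.append(dos.astype(np.int8))
        chroms.append(variant.CHROM)
        pos.append(variant.POS)
    if not rows:
        raise ValueError(f"{path}: no variants")
    locus_map = pd.DataFrame(
        {"chrom": chroms, "pos_cM": pos, "is_qtl": False}
    )
    return np.stack(rows, axis=1), ids, locus_map


def export(
    result: SimResult,
    out_dir: str | Path,
    generations: list[int] | None = None,
    snp_only: bool = True,
) -> list[Path]:
    """Write per-generation genotype, pedigree and locus-map files.

    Genotypes go to ``gen<g>.raw`` (SNP panel only by default, QTL columns
    excluded), the full pedigree/phenotype table to ``pedigree.csv`` and the
    locus map to ``locus_map.csv``.  Returns the written paths; an empty
    generation set writes nothing and warns.
    """
    out = Path(out_dir)
    if generations is None:
        generations = [p.generation for p in result.generations]
    generations = sorted(set(generations))
    known = {p.generation for p in result.generations}
    bad = set(generations) - known
    if bad:
        raise ValueError(f"unknown generations {sorted(bad)}; have {sorted(known)}")
    if not generations:
        warnings.warn("empty generation set: nothing exported")
        return []
    out.mkdir(parents=True, exist_ok=True)
    snp_idx = np.flatnonzero(~result.locus_map["is_qtl"].to_numpy())
    names = [f"snp{i}" for i in snp_idx]
    written = []
    for pop in result.generations:
        if pop.generation not in generations:
            continue
        path = out / f"gen{pop.generation}.raw"
        dos = pop.dosages[:, snp_idx] if snp_only else pop.dosages
        write_plink_raw(path, dos, pop.ids, names if snp_only else None)
        written.append(path)
    ped_path = out / "pedigree.csv"
    write_pedigree(ped_path, result.pedigree())
    map_path = out / "locus_map.csv"
    write_locus_map(map_path, result.locus_map)
    written += [ped_path, map_path]
    return written
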