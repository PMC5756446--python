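"""Readers/writers for the pipeline's file formats.

Supported: PLINK "raw" additive dosage tables (0/1/2, `NA` missing), plain
VCF 4.2 with phased biallelic genotypes, TSV phenotype tables (id, value),
and JSON run manifests with input hashes. VCF reading goes through cyvcf2;
half-calls are treated as missing and multi-allelic records are dropped
with a count.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DosageTable",
    "read_dosage",
    "write_dosage",
    "read_phenotypes",
    "write_phenotypes",
    "write_manifest",
    "read_manifest",
    "verify_inputs",
    "mean_impute",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class DosageTable:
    """Rectangular animal x SNP alt-allele dosage matrix with a map."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float, NaN = missing
    snp_map: pd.DataFrame = field(default=None)  # columns: chrom, id, pos

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("dosage matrix shape must match id lists")
        if len(set(self.sample_ids)) != n or len(set(self.snp_ids)) != m:
            raise ValueError("sample and SNP ids must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.snp_map is None:
            self.snp_map = pd.DataFrame(
                {"chrom": 1, "id": self.snp_ids, "pos": np.arange(m, dtype=float)}
            )


# ------------------------------------------------------------------ PLINK raw


def _write_plink_raw(table: DosageTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(_RAW_META + [f"{s}_A" for s in table.snp_ids]) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = table.dosages[i]
            vals = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + vals) + "\n")


def _read_plink_raw(path: Path) -> DosageTable:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_RAW_META)] != _RAW_META:
            raise ValueError(f"{path}: line 1: not a PLINK raw header (expected {_RAW_META})")
        snp_ids = [c[:-2] if c.endswith("_A") else c for c in header[len(_RAW_META):]]
        n_fields = len(header)
        samples, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            rows.append([np.nan if v == "NA" else float(v) for v in parts[len(_RAW_META):]])
    dos = np.array(rows, dtype=float) if rows else np.empty((0, len(snp_ids)))
    return DosageTable(samples, snp_ids, dos)


# ------------------------------------------------------------------------ VCF


def _write_vcf(table: DosageTable, path: Path) -> None:
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted(set(str(c) for c in table.snp_map["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.sample_ids) + "\n")
        for j, sid in enumerate(table.snp_ids):
            chrom = str(table.snp_map["chrom"].iloc[j])
            # VCF positions are 1-based integers; cM maps are scaled to keep order
            pos = int(round(float(table.snp_map["pos"].iloc[j]) * 10000)) + 1
            gts = "\t".join(
                "./." if np.isnan(v) else gt_of[v] for v in table.dosages[:, j]
            )
            fh.write(f"{chrom}\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def _read_vcf(path: Path) -> DosageTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, poss, cols = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased]
        col = np.full(len(samples), np.nan)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:  # missing or half-call
                continue
            col[i] = float(a0 + a1)
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(float(var.POS))
        cols.append(col)
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: dropped {n_multi} multi-allelic record(s)")
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    snp_map = pd.DataFrame({"chrom": chroms, "id": snp_ids, "pos": poss})
    return DosageTable(samples, snp_ids, dos, snp_map)


# ------------------------------------------------------------------- frontend


def read_dosage(path: str | Path, format: str = "plink_raw") -> DosageTable:
    """Read a dosage table in the named dialect ('plink_raw' or 'vcf')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_dosage(table: DosageTable, path: str | Path, format: str = "plink_raw") -> None:
    path = Path(path)
    if format == "plink_raw":
        _write_plink_raw(table, path)
    elif format == "vcf":
        _write_vcf(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_phenotypes(path: str | Path) -> pd.Series:
    """TSV with columns (id, value); returns a Series indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype table needs at least two columns (id, value)")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].values)


def write_phenotypes(ids, values, path: str | Path) -> None:
    pd.DataFrame({"id": ids, "value": values}).to_csv(path, sep="\t", index=False)


def mean_impute(dosages: np.ndarray, max_missing: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus mean imputation; loci with more than ``max_missing``
    missingness are flagged for dropping. Returns (imputed, keep_mask)."""
    d = np.asarray(dosages, dtype=float).copy()
    miss = np.isnan(d)
    frac = miss.mean(axis=0)
    keep = frac <= max_missing
    col_mean = np.where(miss.all(axis=0), 0.0, np.nanmean(d, axis=0))
    idx = np.where(miss)
    d[idx] = col_mean[idx[1]]
    return d, keep


# -------------------------------------------------------------------- manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(metadata: dict, path: str | Path, input_paths: list | None = None) -> dict:
    """JSON run manifest: config echo, seeds, package version, input hashes."""
    from . import __version__

    manifest = dict(metadata)
    manifest["fstprior_version"] = __version__
    manifest["inputs"] = {
        str(p): _sha256(Path(p)) for p in (input_paths or [])
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def verify_inputs(manifest: dict) -> dict:
    """Re-hash manifest inputs; returns {path: matches} per recorded file."""
    return {p: (Path(p).exists() and _sha256(Path(p)) == h) for p, h in manifest.get("inputs", {}).items()}
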