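"""File formats: genotype matrices, trait vectors, result tables.

Genotypes travel as tab-delimited text with individuals as rows and a header
of SNP identifiers, entries being minor-allele counts 0/1/2; a PLINK-.raw
style dialect (FID IID PAT MAT SEX PHENOTYPE then dosage columns) is also
supported and auto-detected from the header.  Missing genotypes are not
supported: the study design assumes complete data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import GenotypeMatrix

__all__ = [
    "FormatError",
    "read_genotypes",
    "write_genotypes",
    "read_trait",
    "write_trait",
    "write_results",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


def _detect_dialect(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    fields = header.split()
    if fields[: len(_PLINK_META)] == _PLINK_META:
        return "plink_raw"
    return "tsv"


def read_genotypes(path, dialect: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix (0/1/2 minor-allele counts) from delimited text."""
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("tsv", "plink_raw"):
        raise ValueError("dialect must be 'tsv', 'plink_raw' or 'auto'")
    df = pd.read_csv(path, sep=r"\s+")
    if dialect == "plink_raw":
        missing = [c for c in _PLINK_META if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: PLINK .raw dialect lacks columns {missing}")
        individual_ids = df["IID"].astype(str).tolist()
        df = df.drop(columns=_PLINK_META)
        # .raw SNP columns carry the counted allele as a suffix (SNP1_A)
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns]
    else:
        individual_ids = [f"ind{i + 1}" for i in range(len(df))]
        snp_ids = list(df.columns)
    values = df.to_numpy()
    if values.size == 0:
        raise FormatError(f"{path}: no genotype data")
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype {values[r, c]!r} at row {r + 1}, "
            f"column {snp_ids[c]!r} (missing data are not supported)")
    return GenotypeMatrix(values=values.astype(np.int8), snp_ids=snp_ids,
                          individual_ids=individual_ids)


def write_genotypes(G: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype matrix as TSV or PLINK-.raw-style text."""
    path = Path(path)
    df = pd.DataFrame(G.values, columns=G.snp_ids)
    if dialect == "plink_raw":
        meta = pd.DataFrame({
            "FID": G.individual_ids, "IID": G.individual_ids,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9,
        })
        df.columns = [f"{s}_A" for s in G.snp_ids]
        df = pd.concat([meta, df], axis=1)
    elif dialect != "tsv":
        raise ValueError("dialect must be 'tsv' or 'plink_raw'")
    df.to_csv(path, sep="\t", index=False)


def read_trait(path) -> np.ndarray:
    """Read a single-column trait file (optional non-numeric header line)."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                v = float(token)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise FormatError(
                    f"{path}: non-numeric trait value {token!r} on line {lineno}"
                ) from None
            if not np.isfinite(v):
                raise FormatError(f"{path}: non-finite trait value on line {lineno}")
            values.append(v)
    if not values:
        raise FormatError(f"{path}: empty trait file")
    return np.asarray(values, dtype=float)


def write_trait(t, path, header: str | None = "trait") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        for v in np.asarray(t, dtype=float):
            fh.write(f"{v:.10g}\n")


def _config_hash(metadata: dict) -> str:
    return hashlib.sha256(
        json.dumps(metadata, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a result table as TSV plus a JSON metadata sidecar.

    Row and column order are preserved from the table; floats use six
    significant digits; the sidecar records the seed/config and tool version
    so that identical runs produce byte-identical files.
    """
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = dict(metadata or {})
    meta.setdefault("tool", "mbmdr-robust")
    meta.setdefault("version", __version__)
    meta["config_hash"] = _config_hash(meta)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
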