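"""Readers and writers for genotype/phenotype tables and scan results.

Formats (all plain text):

* genotypes: CSV/TSV matrix, rows = individuals (first column
  ``individual_id``), remaining columns = marker ids, values in
  {0, 1, 2, NA};
* marker map (optional): CSV with columns marker_id, chrom, pos;
* longitudinal phenotypes: tidy CSV (individual_id, time, value) or wide
  CSV (individual_id, t<1>..t<T>);
* static phenotype: CSV (individual_id, value);
* scan results: TSV, one marker per row, floats at 6 significant digits,
  with a JSON run manifest written alongside for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .growth import TimeGrid

__all__ = [
    "ScanConfig",
    "read_genotypes",
    "write_genotypes",
    "read_longitudinal",
    "read_static",
    "assemble_dataset",
    "write_results",
    "read_vcf_genotypes",
]

GENO_CODES = {0, 1, 2}


@dataclass
class ScanConfig:
    """Validated configuration for a scan run; serialized next to results."""

    geno: str
    pheno_long: str
    pheno_static: str
    out: str
    marker_map: str | None = None
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    cross_structure: str = "decay"
    subtest_null: str = "chisq"
    min_class_size: int = 5
    threshold_mode: str = "shared"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if self.cross_structure not in ("decay", "constant"):
            raise ValueError("cross_structure must be 'decay' or 'constant'")
        if self.subtest_null not in ("chisq", "permutation"):
            raise ValueError("subtest_null must be 'chisq' or 'permutation'")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_genotypes(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a genotype matrix; returns (matrix, marker_ids, individual_ids).

    Missing calls (NA) become -1; anything outside {0, 1, 2, NA} raises a
    parse error naming the offending row and column.
    """
    df = _read_table(path)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).to_numpy()
    marker_ids = list(df.columns[1:])
    mat = np.full((len(df), len(marker_ids)), -1, dtype=np.int8)
    for j, mcol in enumerate(marker_ids):
        col = df[mcol]
        vals = pd.to_numeric(col, errors="coerce")
        bad = vals.notna() & ~vals.isin(list(GENO_CODES))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid genotype {col.iloc[i]!r} at individual {ids[i]!r}, "
                f"marker {mcol!r}: expected 0/1/2/NA"
            )
        ok = vals.notna().to_numpy()
        mat[ok, j] = vals.to_numpy(dtype=float)[ok].astype(np.int8)
    return mat, marker_ids, ids


def write_genotypes(
    path: str | Path, G: np.ndarray, marker_ids: list[str], ids: np.ndarray
) -> None:
    df = pd.DataFrame(G.astype(object), columns=marker_ids)
    df = df.mask(df < 0, other=pd.NA)
    df.insert(0, "individual_id", ids)
    df.to_csv(path, index=False)


def read_marker_map(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    need = {"marker_id", "chrom", "pos"}
    if not need.issubset(df.columns):
        raise ValueError(f"marker map must have columns {sorted(need)}")
    return df


def read_longitudinal(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read the longitudinal trait; accepts tidy (individual_id, time,
    value) or wide (individual_id, t1..tT) layout.  Returns (ids, times,
    matrix); individuals with any missing time point are dropped
    (complete-case rule)."""
    df = _read_table(path)
    cols = set(df.columns)
    if {"individual_id", "time", "value"}.issubset(cols):
        wide = df.pivot_table(index="individual_id", columns="time", values="value")
    else:
        tcols = [c for c in df.columns[1:]]
        wide = df.set_index(df.columns[0])[tcols]
        wide.columns = [float(str(c).lstrip("t")) for c in tcols]
    wide = wide.sort_index(axis=1).dropna(axis=0, how="any")
    times = np.asarray(wide.columns, dtype=float)
    return wide.index.astype(str).to_numpy(), times, wide.to_numpy(dtype=float)


def read_static(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_table(path)
    ids = df[df.columns[0]].astype(str).to_numpy()
    vals = pd.to_numeric(df[df.columns[1]], errors="coerce").to_numpy()
    keep = np.isfinite(vals)
    return ids[keep], vals[keep]


def assemble_dataset(
    long_ids: np.ndarray,
    times: np.ndarray,
    Y: np.ndarray,
    static_ids: np.ndarray,
    z: np.ndarray,
) -> tuple[LongitudinalDataset, np.ndarray]:
    """Intersect the two phenotype tables on individual id; returns the
    dataset and the ids kept (in dataset row order)."""
    common, li, si = np.intersect1d(long_ids, static_ids, return_indices=True)
    if common.size == 0:
        raise ValueError("no individuals shared between the phenotype tables")
    data = LongitudinalDataset(
        y=Y[li], z=z[si], grid=TimeGrid(times), ids=common
    )
    return data, common


def write_results(
    results, path: str | Path, config: ScanConfig | None = None, extra: dict | None = None
) -> None:
    """Write one TSV row per marker plus a JSON run manifest (.manifest.json)."""
    from . import __version__
    from .scan import results_frame

    df = results_frame(results) if not isinstance(results, pd.DataFrame) else results
    out = Path(path)
    df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    manifest = {"version": __version__, "n_markers": int(len(df))}
    if config is not None:
        manifest["config"] = asdict(config)
    if extra:
        manifest.update(extra)
    out.with_suffix(out.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )


def read_vcf_genotypes(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray, pd.DataFrame]:
    """Convenience shim: biallelic VCF GT fields to a 0/1/2 dosage matrix.

    Returns (matrix, marker_ids, sample_ids, marker_map).  Multiallelic
    records are skipped; missing genotypes become -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows = []
    ids = []
    mmap = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gts == 0, 0, np.where(gts == 1, 1, np.where(gts == 3, 2, -1)))
        rows.append(col.astype(np.int8))
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        ids.append(mid)
        mmap.append({"marker_id": mid, "chrom": var.CHROM, "pos": var.POS})
    G = np.column_stack(rows) if rows else np.empty((samples.size, 0), dtype=np.int8)
    return G, ids, samples, pd.DataFrame(mmap)
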