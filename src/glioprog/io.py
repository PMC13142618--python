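"""Readers and writers for the pipeline's on-disk formats.

MatrixMarket MTX bundles follow the 10x layout (matrix.mtx + barcodes.tsv +
features.tsv, optionally gzipped); on-disk orientation is normalised to
cells x genes by matching matrix dimensions against the id-list lengths.
Gene sets use GMT; tabular outputs are CSV with a metadata comment block
(# key: value lines) ahead of the single header row.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .scoring import GeneSet
from .synthetic import CountMatrix


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {dirpath}")


def _read_tsv_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]


def read_mtx_bundle(dirpath: str | Path) -> CountMatrix:
    """Read a 10x-style MTX bundle into a cells x genes CountMatrix.

    Orientation is inferred from the barcode/feature list lengths; the
    features file may carry a third mito flag column or the flag is derived
    from an MT- name prefix. Non-integer entries are an error.
    """
    dirpath = Path(dirpath)
    mat = sp.csr_matrix(mmread(_find(dirpath, "matrix.mtx")))
    barcodes = _read_tsv_column(_find(dirpath, "barcodes.tsv"))
    fpath = _find(dirpath, "features.tsv")
    features = _read_tsv_column(fpath)

    n_b, n_f = len(barcodes), len(features)
    if mat.shape == (n_b, n_f):
        pass
    elif mat.shape == (n_f, n_b):
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither ({n_b}, {n_f}) nor its transpose"
        )
    if mat.dtype.kind == "f":
        if not np.all(mat.data == np.round(mat.data)):
            raise ValueError("matrix contains non-integer entries")
        mat = mat.astype(np.int64)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("matrix contains negative entries")
    flags = np.array([g.startswith("MT-") for g in features])
    return CountMatrix(
        counts=mat, cell_ids=barcodes, gene_ids=features, gene_flags=flags
    )


def write_mtx_bundle(matrix: CountMatrix, dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    mmwrite(dirpath / "matrix.mtx", sp.coo_matrix(matrix.counts))
    (dirpath / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    with open(dirpath / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], source=parts[1], genes=[g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *s.genes]) + "\n")


def upr_branch_sets() -> list[GeneSet]:
    """The three canonical UPR branch gene sets shipped with the package."""
    from importlib.resources import files

    path = files("glioprog").joinpath("data/upr_branches.gmt")
    with path.open() as fh:
        sets = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(name=parts[0], source=parts[1], genes=parts[2:]))
    return sets


def write_csv_with_metadata(
    df: pd.DataFrame, path: str | Path, metadata: dict, index: bool = True
) -> None:
    """CSV with a leading '# key: value' comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)


def read_csv_with_metadata(path: str | Path, **kwargs) -> tuple[pd.DataFrame, dict]:
    metadata = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("# "):
                key, _, value = line[2:].rstrip("\n").partition(": ")
                metadata[key] = value
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, **kwargs)
    return df, metadata


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
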