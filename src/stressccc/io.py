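"""Plain-text readers and writers for the standard formats used here.

Count matrices travel as a CellRanger-style triplet: ``matrix.mtx``
(MatrixMarket coordinate integer, genes x cells, 1-based indices),
``features.tsv`` and ``barcodes.tsv``, with a separate per-cell
metadata CSV.  Gene-set collections use the GMT dialect
(term_id <tab> term_name <tab> gene...).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import FormatError, ValidationError

CELL_META_COLUMNS = ["mouse", "group", "region", "hemisphere", "cell_type"]


def write_mtx_triplet(outdir, counts, gene_ids, barcodes) -> None:
    """Write a genes x cells integer sparse matrix as an MTX triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(counts)
    spio.mmwrite(os.fspath(outdir / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame(
        {"id": gene_ids, "name": gene_ids, "type": "Gene Expression"}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_mtx_triplet(indir):
    """Read an MTX triplet; returns (csr counts, gene symbols, barcodes)."""
    indir = Path(indir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise FormatError(f"missing {name} in {indir}")
    counts = sparse.csr_matrix(spio.mmread(os.fspath(indir / "matrix.mtx")))
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    genes = feats[0].astype(str).tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {counts.shape} does not match "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    return counts, genes, barcodes


def read_cell_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"cell metadata missing column(s): {missing}")
    return meta


def write_cell_meta(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, index=True, index_label="barcode")


def read_behavior_csv(path) -> pd.DataFrame:
    from .behavior import BEHAVIOR_COLUMNS

    table = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"behavioral table missing column(s): {missing}")
    return table


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {term_id: (term_name, genes)}."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: need id, name and >=1 gene")
            term_id, name, genes = parts[0], parts[1], parts[2:]
            if term_id in out:
                raise ValidationError(f"duplicate GMT term {term_id!r}")
            out[term_id] = (name, frozenset(g.strip() for g in genes if g.strip()))
    if not out:
        raise ValidationError(f"empty GMT file: {path}")
    return out


def write_gmt(path, terms: dict[str, tuple[str, frozenset[str]]]) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in terms.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
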