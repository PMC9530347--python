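"""Readers and writers for the pipeline's on-disk formats.

Counts travel either as a cellranger-style MatrixMarket triplet
(matrix.mtx with genes as rows + genes.tsv + barcodes.tsv) or as a dense
cells x genes CSV.  Gene sets use GMT; annotations, edge lists and DE
tables are plain TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ANNOTATION_COLUMNS, CountMatrix, GeneSignature, Regulon, validate_annotation

__all__ = [
    "write_mtx_triplet",
    "read_mtx_triplet",
    "write_counts_csv",
    "read_counts_csv",
    "write_annotation",
    "read_annotation",
    "write_gmt",
    "read_gmt",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_tf_list",
    "read_tf_list",
]


# ---------------------------------------------------------------------------
# counts

def write_mtx_triplet(counts: CountMatrix, out_dir: str) -> None:
    """Write matrix.mtx (genes x cells) + genes.tsv + barcodes.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    mat = sparse.csr_matrix(counts.values.T)  # genes as rows, cellranger-style
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat, field="integer")
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.writelines(f"{g}\t{g}\n" for g in counts.gene_ids)
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{c}\n" for c in counts.cell_ids)


def read_mtx_triplet(in_dir: str) -> CountMatrix:
    mat = spio.mmread(os.path.join(in_dir, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(in_dir, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None)
    values = np.asarray(sparse.csr_matrix(mat).todense()).T  # back to cells x genes
    return CountMatrix(
        values=values.astype(np.int64),
        cell_ids=list(barcodes[0].astype(str)),
        gene_ids=list(genes[0].astype(str)),
    )


def write_counts_csv(counts: CountMatrix, path: str) -> None:
    counts.to_frame().to_csv(path, index_label="cell_id")


def read_counts_csv(path: str) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        values=df.to_numpy(dtype=np.int64),
        cell_ids=list(df.index.astype(str)),
        gene_ids=list(df.columns.astype(str)),
    )


# ---------------------------------------------------------------------------
# cell annotations

def write_annotation(ann: pd.DataFrame, path: str) -> None:
    cols = [c for c in ann.columns if c in ANNOTATION_COLUMNS or c == "cluster"]
    ann[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# gene sets

def write_gmt(signatures, path: str) -> None:
    """Write signatures or regulons as GMT (name, description, genes...)."""
    with open(path, "w") as fh:
        for sig in signatures:
            if isinstance(sig, Regulon):
                name, desc, genes = sig.tf, "regulon", sig.targets
            else:
                name, desc, genes = sig.name, sig.provenance or ".", sig.genes
            fh.write("\t".join([name, desc or ".", *genes]) + "\n")


def read_gmt(path: str) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            out.append(GeneSignature(name=parts[0], genes=parts[2:], provenance=parts[1]))
    return out


# ---------------------------------------------------------------------------
# edges and TF lists

def write_edges_tsv(edges: pd.DataFrame, path: str) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"edge TSV missing column {col!r}")
    return df


def write_tf_list(tfs, path: str) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{t}\n" for t in tfs)


def read_tf_list(path: str) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
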