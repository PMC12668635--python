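"""Standard-format expression, network and gene-list I/O.

Expression matrices are genes x cells, read either from one CSV/TSV per state
(header row = cell barcodes) or from a MatrixMarket triplet
(``<state>.mtx`` + ``<state>.genes.tsv`` + ``<state>.barcodes.tsv``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = ["load_state_matrix", "load_expression_dir", "load_gene_list"]


def load_state_matrix(expr_dir: Path, state: str) -> pd.DataFrame:
    """Load one state's genes x cells matrix (CSV, TSV or MTX triplet)."""
    expr_dir = Path(expr_dir)
    for suffix, sep in ((".csv", ","), (".tsv", "\t")):
        f = expr_dir / f"{state}{suffix}"
        if f.exists():
            df = pd.read_csv(f, sep=sep, index_col=0)
            df.index = df.index.astype(str)
            return df
    mtx = expr_dir / f"{state}.mtx"
    if mtx.exists():
        genes = (expr_dir / f"{state}.genes.tsv").read_text().split()
        barcodes = (expr_dir / f"{state}.barcodes.tsv").read_text().split()
        mat = mmread(mtx).toarray()
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(f"MTX shape {mat.shape} disagrees with gene/barcode files")
        return pd.DataFrame(mat, index=genes, columns=barcodes)
    raise FileNotFoundError(f"no expression file for state '{state}' in {expr_dir}")


def load_expression_dir(expr_dir, states: list[str]) -> list[pd.DataFrame]:
    """Load matrices for the declared states, aligned to the shared gene set.

    Genes are restricted to the intersection across states, in the first
    state's order; dropped genes are logged. Duplicate gene symbols are an
    error.
    """
    expr_dir = Path(expr_dir)
    if not states:
        raise ValueError("no states declared")
    mats = []
    for s in states:
        df = load_state_matrix(expr_dir, s)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols in state '{s}': {dups[:5]}")
        mats.append(df)
    shared = set(mats[0].index)
    for df in mats[1:]:
        shared &= set(df.index)
    if not shared:
        raise ValueError("states share no genes")
    order = [g for g in mats[0].index if g in shared]
    for s, df in zip(states, mats):
        dropped = len(df) - len(order)
        if dropped:
            logger.info("state '%s': dropped %d genes outside the shared set",
                        s, dropped)
    return [df.loc[order] for df in mats]


def load_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines ignored."""
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}
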