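"""Correspondence analysis of the gene x codon usage matrix.

Genes are rows, the 59 synonymously variable codons are columns (Met, Trp
and stops excluded), and the ordination is classical correspondence
analysis under the chi-square metric: the matrix of relative frequencies
is double-centred and standardised by row/column masses, decomposed by
SVD, and genes are placed in principal coordinates. The fraction of total
inertia carried by each axis measures how dominant each trend in codon
usage is; in selection-shaped genomes the first axis separates putatively
highly from lowly expressed genes.

Axis signs are arbitrary in CA, so :func:`orient_axes` flips axes to make
a chosen reference gene set (typically ribosomal proteins) sit on the
positive side of axis 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GeneticCode, standard_code
from .metrics import CodonCountTable, rscu

logger = logging.getLogger(__name__)


def build_usage_matrix(
    tables: Sequence[CodonCountTable],
    code: GeneticCode | None = None,
    kind: str = "rscu",
) -> pd.DataFrame:
    """Gene x 59-codon matrix of RSCU values or raw counts.

    Columns are the synonymous codons in fixed alphabetical (DNA) order.
    With ``kind='rscu'`` families absent from a gene get 0 (logged), which
    keeps the matrix complete and non-negative. Genes whose row would be
    all zero are excluded with a warning.
    """
    code = code or standard_code()
    if len(tables) < 3:
        raise ValueError("correspondence analysis needs at least 3 genes")
    if kind not in ("rscu", "counts"):
        raise ValueError("kind must be 'rscu' or 'counts'")
    cols = list(code.synonymous_codons)
    rows, index = [], []
    for t in tables:
        if kind == "rscu":
            values = rscu(t, code)
            row = [values[c] for c in cols]
            if any(np.isnan(v) for v in row):
                logger.info("%s: families with no observations set to RSCU 0", t.source)
            row = [0.0 if np.isnan(v) else v for v in row]
        else:
            row = [float(t[c]) for c in cols]
        if not any(row):
            logger.warning("%s: all-zero usage row; gene excluded from ordination", t.source)
            continue
        rows.append(row)
        index.append(t.source)
    return pd.DataFrame(rows, index=index, columns=cols)


@dataclass
class CoaResult:
    """Correspondence-analysis ordination of a usage matrix."""

    gene_coords: pd.DataFrame       # genes x n_axes, principal coordinates
    codon_coords: pd.DataFrame      # codons x n_axes, principal coordinates
    inertia_fraction: np.ndarray    # percent of total inertia per axis
    total_inertia: float
    input_kind: str = "rscu"

    @property
    def n_axes(self) -> int:
        return self.gene_coords.shape[1]


def correspondence_analysis(
    matrix: pd.DataFrame, n_axes: int | None = None, input_kind: str = "rscu"
) -> CoaResult:
    """Classical CA of a non-negative gene x codon matrix.

    All-zero columns are dropped (and logged) before decomposition. Total
    inertia equals the table's Pearson chi-square statistic divided by its
    grand total; per-axis inertia fractions are reported in percent.
    Raises when fewer than two non-degenerate dimensions exist.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("usage matrix must be non-negative")
    col_keep = X.sum(axis=0) > 0
    if not col_keep.all():
        dropped = list(matrix.columns[~col_keep])
        logger.warning("dropping all-zero codon columns: %s", dropped)
        matrix = matrix.loc[:, col_keep]
        X = X[:, col_keep]
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("matrix too small for correspondence analysis")

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    # standardised residuals under the independence model
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(X.shape[0] - 1, X.shape[1] - 1)
    sigma = sigma[:max_axes]
    total_inertia = float((sigma**2).sum())
    if np.count_nonzero(sigma > 1e-12 * max(1.0, sigma[0] if len(sigma) else 0.0)) < 2:
        if total_inertia == 0.0:
            # identical row profiles: a legitimate degenerate case for tests
            n_axes_eff = min(n_axes or 2, max_axes)
            zeros_g = np.zeros((X.shape[0], n_axes_eff))
            zeros_c = np.zeros((X.shape[1], n_axes_eff))
            axes = [f"axis{i + 1}" for i in range(n_axes_eff)]
            return CoaResult(
                pd.DataFrame(zeros_g, index=matrix.index, columns=axes),
                pd.DataFrame(zeros_c, index=matrix.columns, columns=axes),
                np.zeros(n_axes_eff),
                0.0,
                input_kind,
            )
        raise ValueError("usage matrix has rank < 2: too few distinct genes")

    k = min(n_axes or max_axes, max_axes)
    F = (U[:, :max_axes] * sigma) / np.sqrt(r)[:, None]        # gene principal coords
    G = (Vt.T[:, :max_axes] * sigma) / np.sqrt(c)[:, None]     # codon principal coords
    inertia_pct = 100.0 * sigma**2 / total_inertia
    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        gene_coords=pd.DataFrame(F[:, :k], index=matrix.index, columns=axes),
        codon_coords=pd.DataFrame(G[:, :k], index=matrix.columns, columns=axes),
        inertia_fraction=inertia_pct[:k],
        total_inertia=total_inertia,
        input_kind=input_kind,
    )


def orient_axes(coa: CoaResult, reference_ids: Iterable[str], axes: Sequence[int] = (0,)) -> CoaResult:
    """Flip the given axes so the reference genes' mean coordinate is positive.

    CA axis polarity is arbitrary; anchoring axis 1 to a putatively highly
    expressed reference set (ribosomal proteins) makes "high expression"
    the positive end by convention.
    """
    ref = [g for g in reference_ids if g in coa.gene_coords.index]
    if not ref:
        return coa
    for ax in axes:
        col = coa.gene_coords.columns[ax]
        if coa.gene_coords.loc[ref, col].mean() < 0:
            coa.gene_coords[col] *= -1
            coa.codon_coords[col] *= -1
    return coa


def axis_extremes(
    coa: CoaResult, axis: int = 0, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Gene ids at the two extremes of an ordination axis.

    Returns (high ids, low ids): the top and bottom ``ceil(fraction * n)``
    genes by the axis coordinate, ties broken by gene id so the split is
    deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    col = coa.gene_coords.columns[axis]
    n = int(np.ceil(fraction * len(coa.gene_coords)))
    ordered = coa.gene_coords[col].sort_values(
        ascending=False, kind="mergesort"
    )
    # secondary deterministic key on gene id for exact ties
    ordered = (
        pd.DataFrame({"coord": ordered})
        .assign(gene_id=lambda d: d.index)
        .sort_values(["coord", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    ids = list(ordered["gene_id"])
    return ids[:n], list(reversed(ids[-n:]))


def correlate_axes(
    coa: CoaResult,
    profiles: pd.DataFrame,
    indices: Sequence[str] = ("cai", "gc3s", "g3s", "c3s", "a3s", "t3s", "fop"),
    axes: Sequence[int] = (0, 1),
) -> pd.DataFrame:
    """Pearson correlations between ordination axes and usage indices.

    `profiles` must be indexed by gene id and cover every ordinated gene.
    Zero-variance index columns yield ``nan`` (undefined) entries.
    Returns a tidy frame: axis, index, r, p, plus the axis inertia percent.
    """
    aligned = profiles.loc[coa.gene_coords.index]
    out = []
    for ax in axes:
        col = coa.gene_coords.columns[ax]
        coords = coa.gene_coords[col].to_numpy()
        for name in indices:
            x = aligned[name].to_numpy(dtype=float)
            ok = ~np.isnan(x)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(coords[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(coords[ok], x[ok])
            out.append(
                {"axis": ax + 1, "inertia_pct": coa.inertia_fraction[ax], "index": name,
                 "r": r, "p": p}
            )
    return pd.DataFrame(out)
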