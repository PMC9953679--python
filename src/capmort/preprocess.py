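"""RMA-style preprocessing: quantile normalization and median-polish summarization.

Input is assumed to be background-clean log2 intensity data; the normexp
background-correction step of full RMA is deliberately NOT implemented
(it operates on raw probe intensities which this package never sees).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["quantile_normalize", "median_polish", "median_polish_summarize"]


def quantile_normalize(
    matrix: pd.DataFrame, exclude: list[str] | None = None
) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a features x samples matrix.

    After normalization every column has the same empirical distribution:
    the across-column mean of order statistics.  Ties within a column
    receive the mean of the tied reference values ("ties = average").

    Parameters
    ----------
    matrix
        Features x samples table of log2 values, no missing entries.
    exclude
        Optional feature IDs (e.g. control probes) dropped before
        normalization.

    Raises
    ------
    ValueError
        If the matrix contains missing values.
    """
    if exclude:
        matrix = matrix.drop(index=[g for g in exclude if g in matrix.index])
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    if x.shape[1] < 2:
        warnings.warn(
            "quantile normalization with a single column is the identity",
            UserWarning,
            stacklevel=2,
        )
        return matrix.copy()

    order = np.argsort(x, axis=0, kind="stable")
    reference = np.take_along_axis(x, order, axis=0).mean(axis=1)

    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col_sorted_idx = order[:, j]
        vals = np.empty(n)
        vals[col_sorted_idx] = reference
        # average reference values over runs of tied input values
        sorted_vals = x[col_sorted_idx, j]
        run_start = 0
        for k in range(1, n + 1):
            if k == n or sorted_vals[k] != sorted_vals[run_start]:
                if k - run_start > 1:
                    vals[col_sorted_idx[run_start:k]] = reference[run_start:k].mean()
                run_start = k
        out[:, j] = vals

    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    x: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array; rows swept first.

    Fits ``x[i, j] ~ overall + row[i] + col[j]`` by alternately removing
    row and column medians, stopping when the change in the sum of
    absolute residuals falls below ``tol`` or after ``max_iter`` sweeps.

    Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    r = np.asarray(x, dtype=float).copy()
    n_row, n_col = r.shape
    overall = 0.0
    row_eff = np.zeros(n_row)
    col_eff = np.zeros(n_col)
    prev_sar = np.abs(r).sum()
    for _ in range(max_iter):
        row_med = np.median(r, axis=1)
        r -= row_med[:, None]
        row_eff += row_med
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        col_med = np.median(r, axis=0)
        r -= col_med[None, :]
        col_eff += col_med
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        sar = np.abs(r).sum()
        if abs(prev_sar - sar) < tol * (sar if sar > 0 else 1.0) or sar < 1e-12:
            break
        prev_sar = sar
    return overall, row_eff, col_eff, r


def median_polish_summarize(
    probe_matrix: pd.DataFrame, probe_map: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Summarize a probes x samples matrix to gene level by median polish.

    ``probe_map`` maps every probe ID in ``probe_matrix.index`` to a single
    gene symbol (a Series probe->gene, or a two-column DataFrame
    ``[probe, gene]``).  Per gene, an additive model (overall + probe
    effect + sample effect) is fitted robustly and the gene-level value of
    a sample is ``overall + sample_effect``.

    Raises
    ------
    ValueError
        If a probe in the matrix has no gene mapping.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = probe_map.set_index(probe_map.columns[0])[probe_map.columns[1]]
    missing = probe_matrix.index.difference(probe_map.index)
    if len(missing):
        raise ValueError(f"probes without gene mapping: {list(missing[:5])}")

    genes = probe_map.reindex(probe_matrix.index)
    rows = {}
    for gene, sub in probe_matrix.groupby(genes.values, sort=True):
        if sub.shape[0] == 1:
            rows[gene] = sub.iloc[0].to_numpy(dtype=float)
            continue
        overall, _, col_eff, _ = median_polish(sub.to_numpy())
        rows[gene] = overall + col_eff
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.columns)
    out.index.name = "gene"
    return out
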