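"""Microbiome exposure: the log Prevotella/Bacteroides ratio.

The P/B ratio is a one-dimensional summary of gut community state along the
enterotype axis. Zeros are imputed with a pseudocount equal to half of the
smallest non-zero relative abundance observed anywhere in the genus table
(a single global minimum), after which ``log_pb = ln(Prevotella /
Bacteroides)``. Because the pseudocount is derived from the table itself,
the ratio is invariant to the abundance units (percent vs proportion).

An optional rank-based inverse-normal transform (Blom offset 3/8, average
ranks for ties) is provided for the sensitivity analysis that guards
against the bimodality of the raw log ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["compute_log_pb", "rank_inverse_normal", "read_genus_table"]


def _find_genus_column(columns, genus):
    target = genus.lower()
    for col in columns:
        low = str(col).lower()
        if low == target or low.endswith(f"__{target}") or low.endswith(f"g__{target}"):
            return col
    raise ValueError(f"genus column {genus!r} not found in abundance table")


def compute_log_pb(table, prevotella="Prevotella", bacteroides="Bacteroides"):
    """Compute per-person log P/B ratios from a wide genus table.

    Parameters
    ----------
    table : DataFrame
        Rows are persons (identified by a ``person_id`` column, else by the
        index); remaining numeric columns are genus relative abundances.
    prevotella, bacteroides : str
        Genus column names; MetaPhlAn-style ``k__...|g__Prevotella`` labels
        are matched on the genus suffix.

    Returns
    -------
    DataFrame with columns ``person_id`` and ``log_pb`` (natural log).

    Raises
    ------
    ValueError
        If a genus column is missing, any abundance is negative, or the
        table contains no non-zero value (pseudocount undefined).
    """
    if "person_id" in table.columns:
        person_id = table["person_id"].to_numpy()
        values = table.drop(columns=["person_id"])
    else:
        person_id = table.index.to_numpy()
        values = table
    if pd.Index(person_id).duplicated().any():
        raise ValueError("duplicate person_id in abundance table")

    values = values.apply(pd.to_numeric)
    mat = values.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("relative abundances must be non-negative")
    nonzero = mat[mat > 0]
    if nonzero.size == 0:
        raise ValueError("abundance table is all zero; pseudocount undefined")
    pseudocount = nonzero.min() / 2.0

    p_col = _find_genus_column(values.columns, prevotella)
    b_col = _find_genus_column(values.columns, bacteroides)
    p = values[p_col].to_numpy(dtype=float)
    b = values[b_col].to_numpy(dtype=float)
    p = np.where(p > 0, p, pseudocount)
    b = np.where(b > 0, b, pseudocount)
    return pd.DataFrame({"person_id": person_id, "log_pb": np.log(p / b)})


def rank_inverse_normal(values, offset=0.375):
    """Rank-based inverse-normal transform, Phi^-1((r - c) / (n + 1 - 2c)).

    Uses average ranks for ties and the Blom offset c = 3/8 by default. The
    output depends on the input only through its ranks, so any strictly
    monotone transform of the input yields the same result.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.ptp(arr) == 0:
        raise ValueError("constant vector: all values tied, transform undefined")
    n = arr.size
    ranks = rankdata(arr, method="average")
    return norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def read_genus_table(path, sep="\t"):
    """Read a genus abundance TSV into wide (persons-as-rows) form.

    Accepts either a plain wide table with a ``person_id`` column, or a
    MetaPhlAn-style orientation with taxa as rows (first column named e.g.
    ``clade_name`` or containing ``g__`` labels), which is transposed and
    the genus name extracted from the last ``g__`` component.
    """
    df = pd.read_csv(path, sep=sep)
    first = df.columns[0]
    taxa_first_col = str(first).lower() in {"clade_name", "taxon", "taxonomy", "genus", "#otu id"}
    if not taxa_first_col and df[first].dtype == object:
        taxa_first_col = df[first].astype(str).str.contains("g__").any()
    if not taxa_first_col:
        if "person_id" not in df.columns:
            df = df.rename(columns={first: "person_id"})
        return df
    wide = df.set_index(first).T
    wide.columns = [str(c).split("g__")[-1].split("|")[0] for c in wide.columns]
    wide = wide.apply(pd.to_numeric)
    wide.insert(0, "person_id", wide.index)
    return wide.reset_index(drop=True)
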