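"""Genus count tables: loading, prevalence filtering and CLR transformation.

A genus count matrix is a pandas DataFrame of non-negative integers with one
row per sample (index = unique sample ids) and one column per genus. The
centered log-ratio (CLR) transform maps each compositional row to a zero-sum
real vector, log(x_j) - mean_j log(x_j), so that ordinary linear models can
be applied to relative-abundance data without the unit-sum constraint
inducing spurious correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr


def validate_counts(counts: pd.DataFrame) -> None:
    """Check count-matrix invariants, raising ``ValueError`` on violation."""
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate genus name: {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    if np.isnan(values.astype(float)).any():
        raise ValueError("count matrix contains missing cells")
    if (values < 0).any():
        raise ValueError("count matrix contains negative cells")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integer cells")


def load_counts(path) -> pd.DataFrame:
    """Load a samples x genera count table from TSV/CSV.

    The first column holds sample ids; the header row holds genus names.
    Delimiter is inferred from the extension (``.csv`` -> comma, otherwise
    tab). Raises ``ValueError`` for ragged rows (with the line number pandas
    reports), duplicate sample ids, or negative/non-integer cells.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # pandas message includes the line
        raise ValueError(f"malformed count table {path}: {exc}") from exc
    validate_counts(df)
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    counts.to_csv(path, sep=sep)


def prevalence_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Keep genera present (count > 0) in >= ``threshold`` of samples of EVERY group.

    ``groups`` maps each sample id to its exposure-group label; every sample
    in ``counts`` must be labelled, and every group must be non-empty. Column
    order of retained genera is preserved. The default 0.5 keeps "common"
    genera detected in at least half the participants of each group, so that
    group contrasts are not driven by presence/absence structure.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    groups = groups.reindex(counts.index)
    if groups.isna().any():
        missing = counts.index[groups.isna()][0]
        raise ValueError(f"sample {missing!r} has no group label")
    keep = np.ones(counts.shape[1], dtype=bool)
    present = counts.to_numpy() > 0
    for label, idx in groups.groupby(groups).groups.items():
        rows = counts.index.get_indexer(idx)
        if len(rows) == 0:
            raise ValueError(f"group {label!r} has zero samples")
        keep &= present[rows].mean(axis=0) >= threshold
    return counts.loc[:, counts.columns[keep]]


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a count matrix.

    ``value[i, j] = ln(c[i, j] + pseudocount) - mean_j ln(c[i, .] + pseudocount)``.

    A uniform pseudocount (default 1) handles zero counts; it must be
    positive whenever zeros are present. Every output row sums to zero.
    """
    values = counts.to_numpy(dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (values <= 0).any():
        raise ValueError("zero counts present: a positive pseudocount is required")
    transformed = _skbio_clr(values + pseudocount)
    return pd.DataFrame(transformed, index=counts.index, columns=counts.columns)
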