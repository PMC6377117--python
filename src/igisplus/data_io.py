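"""Expression-matrix I/O, unit-interval rescaling and three-state discretization.

The information-theoretic filter operates on genes discretized into three
states at the per-gene positions mu - sigma and mu + sigma: a value below
mu - sigma maps to -1, above mu + sigma to +1, and 0 otherwise (boundary
values inclusive map to 0). Classifiers always see the un-discretized,
rescaled values; only the filter criterion uses the states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledExpressionMatrix",
    "DiscretizedMatrix",
    "load_dataset",
    "save_dataset",
    "rescale_unit_interval",
    "discretize",
]


class DataValidationError(ValueError):
    """Raised when an input matrix or label vector violates the data contract."""


@dataclass
class LabeledExpressionMatrix:
    """A samples x genes real-valued expression matrix with class labels.

    Parameters
    ----------
    values : ndarray, shape (M, N)
        Expression values, one row per sample, one column per gene.
    gene_ids : sequence of str
        N unique gene identifiers.
    labels : ndarray, shape (M,)
        Class label per sample (2-5 distinct classes, each with >= 2 members).
    sample_ids : sequence of str, optional
        Sample identifiers; generated as ``s0..s{M-1}`` when omitted.
    """

    values: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D samples x genes matrix")
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise DataValidationError(f"need at least 2 samples and 1 gene, got {m}x{n}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite value at sample row {bad[0]}, gene column {bad[1]}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != n:
            raise DataValidationError(
                f"{len(self.gene_ids)} gene ids for {n} gene columns"
            )
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.labels.shape != (m,):
            raise DataValidationError(
                f"{self.labels.shape[0] if self.labels.ndim == 1 else '?'} labels "
                f"for {m} samples"
            )
        classes, counts = np.unique(self.labels, return_counts=True)
        if not 2 <= classes.size <= 5:
            raise DataValidationError(
                f"need 2-5 classes, found {classes.size}"
            )
        if counts.min() < 2:
            small = classes[counts < 2]
            raise DataValidationError(f"classes with < 2 samples: {list(small)}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(m)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != m:
                raise DataValidationError(
                    f"{len(self.sample_ids)} sample ids for {m} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_rows(self, rows: np.ndarray) -> "LabeledExpressionMatrix":
        """A copy restricted to the given sample rows (order preserved)."""
        rows = np.asarray(rows)
        return LabeledExpressionMatrix(
            values=self.values[rows].copy(),
            gene_ids=list(self.gene_ids),
            labels=self.labels[rows].copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass
class DiscretizedMatrix:
    """Three-state view of an expression matrix.

    ``states[i, g]`` is -1, 0 or +1 depending on where sample i's value for
    gene g falls relative to that gene's thresholds ``(lower[g], upper[g])``
    = (mu_g - sigma_g, mu_g + sigma_g).
    """

    states: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    stats_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise DataValidationError("states must lie in {-1, 0, +1}")


def _parse_matrix_file(matrix_path: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise
    # locate any non-numeric cell so the error names its position
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise DataValidationError(
            f"non-numeric cell at row {row!r}, column {col!r}: {frame.loc[row, col]!r}"
        )
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0).idxmax()
        row = numeric[col].isna().idxmax()
        raise DataValidationError(f"missing value at row {row!r}, column {col!r}")
    return numeric


def load_dataset(
    matrix_path: str,
    labels_path: str | None = None,
    *,
    label_column: str = "class",
    orientation: str = "auto",
) -> LabeledExpressionMatrix:
    """Read a tab-delimited expression table plus class labels.

    The table's first row holds identifiers and its first column holds the
    other axis's identifiers. Labels come either from ``labels_path`` (one
    label per line, aligned with samples) or from a column of the table named
    ``label_column``.

    Parameters
    ----------
    orientation : {"auto", "samples", "genes"}
        Which axis the file's *rows* represent. ``auto`` uses the label count
        when available, otherwise assumes the longer axis is genes (microarray
        files have far more genes than samples).
    """
    frame = _parse_matrix_file(matrix_path)

    labels: np.ndarray | None = None
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = np.asarray([line.strip() for line in fh if line.strip() != ""])

    if orientation not in ("auto", "samples", "genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows_are_samples: bool
    if orientation == "samples":
        rows_are_samples = True
    elif orientation == "genes":
        rows_are_samples = False
    elif labels is None and label_column in frame.columns:
        rows_are_samples = True  # an embedded label column implies samples x genes
    elif labels is not None and len(labels) in frame.shape:
        # whichever axis matches the number of labels is the sample axis
        rows_are_samples = frame.shape[0] == len(labels)
        if frame.shape[0] == frame.shape[1]:
            rows_are_samples = True
    else:
        rows_are_samples = frame.shape[0] <= frame.shape[1]
    if not rows_are_samples:
        frame = frame.T

    if labels is None:
        if label_column not in frame.columns:
            raise DataValidationError(
                f"no labels file given and no {label_column!r} column in the table"
            )
        labels = frame[label_column].to_numpy()
        frame = frame.drop(columns=[label_column])
    if len(labels) != frame.shape[0]:
        raise DataValidationError(
            f"{len(labels)} labels for {frame.shape[0]} samples"
        )

    # integer-valued labels are normalized to ints so '1' and 1 compare equal
    try:
        labels = labels.astype(int)
    except (ValueError, TypeError):
        pass

    return LabeledExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        gene_ids=[str(c) for c in frame.columns],
        labels=labels,
        sample_ids=[str(i) for i in frame.index],
    )


def save_dataset(
    data: LabeledExpressionMatrix,
    matrix_path: str,
    labels_path: str | None = None,
    *,
    label_column: str = "class",
) -> None:
    """Write the tab-delimited format :func:`load_dataset` reads.

    With ``labels_path`` the labels go to their own one-per-line file;
    otherwise they are embedded as a final ``label_column`` column.
    """
    frame = pd.DataFrame(
        data.values, index=data.sample_ids, columns=data.gene_ids
    )
    if labels_path is None:
        frame[label_column] = data.labels
    frame.to_csv(matrix_path, sep="\t", index_label="sample")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for lab in data.labels:
                fh.write(f"{lab}\n")


def rescale_unit_interval(
    data: LabeledExpressionMatrix,
    stats_rows: np.ndarray | None = None,
) -> LabeledExpressionMatrix:
    """Min-max rescale each gene independently to the unit interval.

    A constant gene maps to all zeros, keeping it inert for distance-based
    classifiers. When ``stats_rows`` is given, the per-gene min and max are
    computed on those rows only and the affine map is applied to every row
    (values outside the stats range then fall outside [0, 1]; no clipping).
    """
    ref = data.values if stats_rows is None else data.values[np.asarray(stats_rows)]
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (data.values - lo) / safe
    scaled[:, span == 0] = 0.0
    return LabeledExpressionMatrix(
        values=scaled,
        gene_ids=list(data.gene_ids),
        labels=data.labels.copy(),
        sample_ids=list(data.sample_ids),
    )


def discretize(
    data: LabeledExpressionMatrix | np.ndarray,
    stats_rows: np.ndarray | None = None,
    *,
    ddof: int = 1,
) -> DiscretizedMatrix:
    """Map every gene to three states at the thresholds mu_g +/- sigma_g.

    Parameters
    ----------
    data : LabeledExpressionMatrix or ndarray
        Expression values (all rows are mapped through the thresholds).
    stats_rows : array of sample indices, optional
        Rows over which mu_g and sigma_g are computed (defaults to all rows).
        In a nested cross-validation these are the outer-loop training rows,
        so held-out samples never influence the thresholds.
    ddof : int
        Delta degrees of freedom for sigma; the default 1 (sample standard
        deviation) matches common statistical software.
    """
    values = data.values if isinstance(data, LabeledExpressionMatrix) else np.asarray(data, float)
    if stats_rows is None:
        stats = values
        stats_rows = np.arange(values.shape[0])
    else:
        stats_rows = np.asarray(stats_rows)
        if stats_rows.size == 0:
            raise ValueError("stats_rows must be non-empty")
        stats = values[stats_rows]
    mu = stats.mean(axis=0)
    sigma = stats.std(axis=0, ddof=ddof) if stats.shape[0] > ddof else np.zeros_like(mu)
    lower = mu - sigma
    upper = mu + sigma
    states = np.zeros(values.shape, dtype=np.int8)
    states[values < lower] = -1
    states[values > upper] = 1
    return DiscretizedMatrix(states=states, lower=lower, upper=upper, stats_rows=stats_rows)
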