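"""Core in-memory containers shared across pipeline stages.

All matrices are dense pandas DataFrames with string axes:
TF x gene for regulatory networks and priors, gene x sample for
expression, TF x TF for protein-protein interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file or container contents."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    ``kind`` distinguishes raw counts from covariate-adjusted residuals;
    counts must be non-negative. Gene names may contain duplicates right
    after reading a file (they are collapsed by
    :func:`diffpanda.preprocess.collapse_duplicates`), sample names must
    be unique.
    """

    values: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "residuals"):
            raise ValueError(f"kind must be 'counts' or 'residuals', got {self.kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample names: {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.kind == "counts" and (arr < 0).any():
            raise FormatError("negative entries in a counts matrix")
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            warnings.warn(
                f"duplicate gene identifiers retained: {dupes}; "
                "collapse with preprocess.collapse_duplicates",
                stacklevel=2,
            )

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def validate_covariates(covariates: pd.DataFrame, expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check a covariate table: sample index, a two-level ``diagnosis``
    column, no missing entries; optionally check alignment to an
    expression matrix."""
    if "diagnosis" not in covariates.columns:
        raise FormatError("covariate table lacks a 'diagnosis' column")
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise FormatError(f"missing values in covariate columns: {bad}")
    levels = pd.unique(covariates["diagnosis"])
    if len(levels) != 2:
        raise FormatError(
            f"diagnosis must have exactly 2 observed levels, got {list(levels)}"
        )
    if covariates.index.duplicated().any():
        raise FormatError("duplicate sample names in covariate table")
    if expr is not None:
        missing = [s for s in expr.sample_names if s not in covariates.index]
        if missing:
            raise FormatError(f"samples missing from covariate table: {missing}")
        covariates = covariates.loc[expr.sample_names]
    return covariates


@dataclass
class PriorNetwork:
    """Binary TF x gene motif prior (1 = binding motif in promoter)."""

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.weights.to_numpy()
        if not np.isin(arr, (0.0, 1.0)).all():
            raise FormatError("motif prior must be binary after load")
        if self.weights.index.duplicated().any() or self.weights.columns.duplicated().any():
            raise FormatError("duplicate TF or gene names in motif prior")

    @property
    def tf_names(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_names(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class PPIMatrix:
    """Symmetric TF x TF interaction matrix.

    ``scores`` are in [0, 1] (STRING-style combined confidence) or binary
    once a confidence threshold has been applied; the threshold used is
    recorded in ``threshold_applied``.
    """

    scores: pd.DataFrame
    threshold_applied: float | None = None

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if list(self.scores.index) != list(self.scores.columns):
            raise FormatError("PPI matrix axes differ")
        if not np.allclose(arr, arr.T):
            raise FormatError("PPI matrix is not symmetric")
        if arr.min() < 0 or arr.max() > 1:
            raise FormatError("PPI scores outside [0, 1]")
        if self.threshold_applied is not None and not np.allclose(np.diag(arr), 1.0):
            raise FormatError("binarised PPI must have unit diagonal")

    @property
    def tf_names(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RegulatoryNetwork:
    """PANDA output: TF x gene edge z-scores plus convergence report."""

    weights: pd.DataFrame
    n_iterations: int = 0
    converged: bool = True
    final_hamming: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("regulatory network contains non-finite edge weights")

    @property
    def tf_names(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_names(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class DifferentialNetwork:
    """Case-minus-control edge differences and derived targeting scores.

    ``gene_targeting`` is the differential weighted in-degree (column sums
    of ``delta``); ``tf_targeting`` the differential weighted out-degree
    (row sums). Positive values mean increased targeting in cases.
    """

    delta: pd.DataFrame
    gene_targeting: pd.Series
    tf_targeting: pd.Series

    @property
    def tf_names(self) -> list[str]:
        return list(self.delta.index)

    @property
    def gene_names(self) -> list[str]:
        return list(self.delta.columns)


@dataclass
class Signature:
    """Signed TF signature: TFs with increased (positive) and decreased
    (negative) targeting, each list ordered by effect size."""

    name: str
    positive: list[str]
    negative: list[str]
    k: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"TFs in both signature halves: {sorted(overlap)}")
        if self.k is not None and (len(self.positive) > self.k or len(self.negative) > self.k):
            raise ValueError("signature half exceeds its stated half-size k")

    @property
    def members(self) -> list[str]:
        return list(self.positive) + list(self.negative)

    def is_empty(self) -> bool:
        return not self.positive and not self.negative


@dataclass
class DrugSignatureDB:
    """Named drug signatures queried by cosine reversal."""

    drugs: dict[str, Signature]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sig in self.drugs.items():
            if not isinstance(sig, Signature):
                raise TypeError(f"drug {name!r} is not a Signature")

    @property
    def vocabulary(self) -> list[str]:
        vocab: set[str] = set()
        for sig in self.drugs.values():
            vocab.update(sig.positive)
            vocab.update(sig.negative)
        return sorted(vocab)

    def __len__(self) -> int:
        return len(self.drugs)
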