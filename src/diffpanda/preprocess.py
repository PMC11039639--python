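"""Expression preprocessing: CPM filtering, duplicate collapsing,
covariate residualisation and Pearson co-expression.

The residualisation regresses every gene on all covariates by ordinary
least squares and adds the fitted diagnosis effect and intercept back to
the residuals, so group structure survives while nuisance effects
(batch, age, QC metrics, ...) are removed. Raw counts are never
between-sample normalised: library size is used only inside the CPM
filtering rule.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_covariates


def cpm_filter(
    expr: ExpressionMatrix,
    cpm_threshold: float = 0.5,
    sample_fraction: float = 0.3,
) -> ExpressionMatrix:
    """Keep genes expressed above ``cpm_threshold`` counts-per-million in
    at least ``ceil(sample_fraction * n_samples)`` samples.

    CPM uses raw library sizes (column sums); the returned matrix holds
    the original raw counts of the kept genes.
    """
    if expr.kind != "counts":
        raise ValueError("cpm_filter expects a counts matrix")
    counts = expr.values.to_numpy()
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [expr.sample_names[i] for i in np.nonzero(lib == 0)[0]]
        raise ValueError(f"all-zero sample column(s), CPM undefined: {bad}")
    cpm = counts / lib[None, :] * 1e6
    required = math.ceil(sample_fraction * expr.n_samples)
    keep = (cpm > cpm_threshold).sum(axis=1) >= required
    return ExpressionMatrix(expr.values.loc[keep], kind="counts")


def collapse_duplicates(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a gene ID (order of first occurrence kept)
    and drop genes with no counts at all."""
    df = expr.values
    if df.index.duplicated().any():
        order = df.index.drop_duplicates()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # container warns about dupes
            df = df.groupby(level=0, sort=False).mean().loc[order]
    nonzero = (df.to_numpy() != 0).any(axis=1)
    return ExpressionMatrix(df.loc[nonzero], kind=expr.kind)


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) of a counts matrix.

    Linear-model residualisation and Pearson co-expression both assume
    roughly additive, homoskedastic signals, which counts only approach
    on the log scale; this is a within-gene monotone transform, not a
    between-sample normalisation (library sizes are untouched).
    """
    if expr.kind != "counts":
        raise ValueError("log_transform expects a counts matrix")
    return ExpressionMatrix(np.log2(expr.values + pseudocount), kind="counts")


def _design_matrix(
    covariates: pd.DataFrame, columns: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build an intercept + dummy-coded design; returns the matrix, the
    column labels and a map covariate -> its design-column indices."""
    blocks: list[np.ndarray] = [np.ones((len(covariates), 1))]
    labels = ["intercept"]
    col_map: dict[str, list[int]] = {}
    pos = 1
    for name in columns:
        col = covariates[name]
        if np.issubdtype(col.dtype, np.number):
            block = col.to_numpy(dtype=float)[:, None]
            sub = [name]
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
            block = dummies.to_numpy()
            sub = [f"{name}[{lvl}]" for lvl in dummies.columns]
        blocks.append(block)
        labels.extend(sub)
        col_map[name] = list(range(pos, pos + block.shape[1]))
        pos += block.shape[1]
    return np.hstack(blocks), labels, col_map


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate an aliased pair for the error message
        q, r = np.linalg.qr(X)
        aliased = [labels[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"collinear covariates (rank {rank} < {X.shape[1]}): "
                         f"aliased columns {aliased}")


def residualize(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame,
    keep: str = "diagnosis",
) -> ExpressionMatrix:
    """Remove all covariate effects except ``keep`` from every gene.

    Per gene: fit ``y = intercept + beta_keep + sum(beta_nuisance)`` by
    least squares and return ``intercept + beta_keep * keep + residual``,
    i.e. the nuisance effects are subtracted while the kept effect and
    the intercept are added back.
    """
    covariates = validate_covariates(covariates, expr)
    if keep not in covariates.columns:
        raise ValueError(f"keep column {keep!r} not in covariate table")
    columns = [keep] + [c for c in covariates.columns if c != keep]
    X, labels, col_map = _design_matrix(covariates, columns)
    _check_full_rank(X, labels)

    Y = expr.values.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    kept_cols = [0] + col_map[keep]  # intercept + diagnosis effect
    kept_part = X[:, kept_cols] @ beta[kept_cols, :]
    out = (Y - fitted + kept_part).T
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_names, columns=expr.sample_names),
        kind="residuals",
    )


def variance_partition(
    expr: ExpressionMatrix, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene fraction of variance attributed to each covariate and to
    the residual.

    A fixed-effects linear model on all covariates is fitted per gene;
    the attribution is the R-squared increment of each covariate averaged
    over all covariate orderings (Shapley decomposition), which reduces
    to the sequential increment when the design is orthogonal. Fractions
    are non-negative up to numerical noise and sum to 1.
    """
    covariates = validate_covariates(covariates, expr)
    columns = list(covariates.columns)
    if len(columns) > 8:
        raise ValueError("Shapley attribution over >8 covariates is intractable")
    X, labels, col_map = _design_matrix(covariates, columns)
    _check_full_rank(X, labels)

    Y = expr.values.to_numpy().T  # samples x genes
    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc**2).sum(axis=0)
    tss = np.where(tss == 0, 1.0, tss)  # constant genes: all residual

    def rss(subset: tuple[str, ...]) -> np.ndarray:
        cols = [0] + sorted(i for name in subset for i in col_map[name])
        beta, *_ = np.linalg.lstsq(X[:, cols], Y, rcond=None)
        resid = Y - X[:, cols] @ beta
        return (resid**2).sum(axis=0)

    cache: dict[tuple[str, ...], np.ndarray] = {}
    for r in range(len(columns) + 1):
        for subset in itertools.combinations(columns, r):
            cache[tuple(sorted(subset))] = rss(subset)

    n_genes = Y.shape[1]
    shares = {name: np.zeros(n_genes) for name in columns}
    perms = list(itertools.permutations(columns))
    for perm in perms:
        seen: tuple[str, ...] = ()
        for name in perm:
            before = cache[tuple(sorted(seen))]
            after = cache[tuple(sorted(seen + (name,)))]
            shares[name] += (before - after) / tss
            seen = seen + (name,)
    for name in columns:
        shares[name] /= len(perms)

    result = pd.DataFrame(shares, index=expr.gene_names)
    result["residual"] = 1.0 - result.sum(axis=1)
    return result


def pearson_coexpression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix.

    Zero-variance genes get correlation 0 off-diagonal and 1 on the
    diagonal so downstream consumers always see finite values.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    arr = expr.values.to_numpy()
    sd = arr.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=2,
        )
    safe = arr.copy()
    safe[flat] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(safe)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.gene_names, columns=expr.gene_names)
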