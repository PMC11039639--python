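"""Legacy PANDA message passing.

PANDA (Passing Attributes between Networks for Data Assimilation)
integrates three evidence layers — a binary TF-gene motif prior W, a
TF-TF protein interaction matrix P and a gene-gene co-expression matrix
C — into a weighted bipartite regulatory network. Each layer is first
z-score normalised; the network is then refined by message passing:

* responsibility ``R = T(P, W)`` asks whether TFs that interact also
  share targets,
* availability ``A = T(W, C)`` asks whether co-expressed genes share
  regulators,
* ``W <- (1 - alpha) W + alpha (R + A) / 2`` mixes the messages in with
  learning rate alpha, and P and C are updated towards the co-regulation
  patterns implied by the current W.

``T`` is a continuous Tanimoto similarity kernel. Iteration stops when
the mean absolute difference between W and its message candidate falls
below the tolerance. The result's edge weights are on a z-score scale:
larger values mean more concordant evidence for the TF-gene edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PPIMatrix, PriorNetwork, RegulatoryNetwork
from .preprocess import pearson_coexpression

_EPS = 1e-10  # floor for Tanimoto denominators


@dataclass(frozen=True)
class PandaParams:
    """Message-passing hyperparameters (legacy mode).

    alpha: learning rate in (0, 1]; tolerance: convergence threshold on
    the mean absolute difference between W and its update candidate;
    max_iter: iteration cap.
    """

    alpha: float = 0.1
    tolerance: float = 0.001
    max_iter: int = 200
    mode: str = "legacy"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.mode != "legacy":
            raise ValueError("only legacy mode is implemented")


def t_normalize(M: np.ndarray) -> np.ndarray:
    """Combined row/column z-score normalisation: ``(Zrow + Zcol)/sqrt(2)``
    with population (ddof=0) standard deviations. Rows or columns with
    zero spread contribute 0 rather than NaN so constant priors cannot
    poison the run."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(M).all():
        raise ValueError("non-finite entries")
    row_mu = M.mean(axis=1, keepdims=True)
    row_sd = M.std(axis=1, keepdims=True)
    col_mu = M.mean(axis=0, keepdims=True)
    col_sd = M.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        zrow = np.where(row_sd > 0, (M - row_mu) / row_sd, 0.0)
        zcol = np.where(col_sd > 0, (M - col_mu) / col_sd, 0.0)
    return (zrow + zcol) / np.sqrt(2.0)


def tanimoto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto kernel
    ``T(i,j) = (XY)_ij / sqrt(|X_i.|^2 + |Y_.j|^2 - |(XY)_ij|)``,
    with the denominator floored at a small epsilon."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[0]:
        raise ValueError(f"inner dimensions disagree: {X.shape} x {Y.shape}")
    A = X @ Y
    row_norm = (X * X).sum(axis=1)
    col_norm = (Y * Y).sum(axis=0)
    den = np.sqrt(np.maximum(row_norm[:, None] + col_norm[None, :] - np.abs(A), _EPS))
    return A / den


def _update_diagonal(M: np.ndarray, num: int, alpha: float, step: int) -> np.ndarray:
    """Legacy diagonal refill for the P/C self-similarity updates: the
    diagonal becomes the sample std (ddof=1) of the off-diagonal row
    entries, scaled by the axis size and exp(2*alpha*step)."""
    out = M.copy()
    np.fill_diagonal(out, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(out, axis=1, ddof=1)
    sd = np.nan_to_num(sd)
    np.fill_diagonal(out, sd * num * np.exp(2.0 * alpha * step))
    return out


def prepare_inputs(
    motif: PriorNetwork,
    ppi: PPIMatrix,
    expr: ExpressionMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Intersect the three evidence layers onto shared, sorted axes.

    TFs are restricted to those present in both the motif prior and the
    PPI; genes to those present in both the motif prior and the
    expression matrix (remove-missing semantics). Co-expression is
    computed on the gene intersection.
    """
    tfs = sorted(set(motif.tf_names) & set(ppi.tf_names))
    genes = sorted(set(motif.gene_names) & set(expr.gene_names))
    if not tfs:
        raise ValueError("no TFs shared between motif prior and PPI")
    if not genes:
        raise ValueError("no genes shared between motif prior and expression")
    motif_aligned = motif.weights.loc[tfs, genes]
    ppi_aligned = ppi.scores.loc[tfs, tfs]
    expr_sub = ExpressionMatrix(expr.values.loc[genes], kind=expr.kind)
    coexpr = pearson_coexpression(expr_sub)
    return motif_aligned, ppi_aligned, coexpr


def panda(
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    coexpr: pd.DataFrame,
    params: PandaParams | None = None,
) -> RegulatoryNetwork:
    """Run legacy PANDA message passing on aligned inputs.

    ``motif`` is TF x gene, ``ppi`` TF x TF, ``coexpr`` gene x gene, all
    sharing axes as produced by :func:`prepare_inputs`. Deterministic:
    no randomness anywhere. Returns the final W as edge z-scores plus a
    convergence report; non-convergence within ``max_iter`` is returned
    (with a warning), not raised.
    """
    params = params or PandaParams()
    tf_names = list(motif.index)
    gene_names = list(motif.columns)
    if list(ppi.index) != tf_names or list(ppi.columns) != tf_names:
        raise ValueError("PPI axes do not match motif TF axis")
    if list(coexpr.index) != gene_names or list(coexpr.columns) != gene_names:
        raise ValueError("co-expression axes do not match motif gene axis")
    C0 = coexpr.to_numpy(dtype=float)
    if not np.allclose(C0, C0.T):
        raise ValueError("co-expression matrix must be symmetric")

    n_tfs, n_genes = len(tf_names), len(gene_names)
    W = t_normalize(motif.to_numpy(dtype=float))
    P = t_normalize(ppi.to_numpy(dtype=float))
    C = t_normalize(C0)

    alpha = params.alpha
    hamming = np.inf
    step = 0
    while hamming > params.tolerance and step < params.max_iter:
        responsibility = tanimoto(P, W)
        availability = tanimoto(W, C.T)
        candidate = 0.5 * (responsibility + availability)
        hamming = float(np.abs(W - candidate).mean())
        W = (1 - alpha) * W + alpha * candidate
        if not np.isfinite(W).all():
            raise FloatingPointError(f"non-finite edge weights at iteration {step}")
        if hamming > params.tolerance:
            ppi_update = _update_diagonal(tanimoto(W, W.T), n_tfs, alpha, step)
            P = (1 - alpha) * P + alpha * ppi_update
            coexpr_update = _update_diagonal(tanimoto(W.T, W), n_genes, alpha, step)
            C = (1 - alpha) * C + alpha * coexpr_update
            if not (np.isfinite(P).all() and np.isfinite(C).all()):
                raise FloatingPointError(f"non-finite message matrix at iteration {step}")
        step += 1

    converged = bool(hamming <= params.tolerance)
    if not converged:
        warnings.warn(
            f"PANDA did not converge in {params.max_iter} iterations "
            f"(final hamming {hamming:.3g})",
            stacklevel=2,
        )
    return RegulatoryNetwork(
        weights=pd.DataFrame(W, index=tf_names, columns=gene_names),
        n_iterations=step,
        converged=converged,
        final_hamming=hamming,
    )


def run_panda(
    motif: PriorNetwork,
    ppi: PPIMatrix,
    expr: ExpressionMatrix,
    params: PandaParams | None = None,
) -> RegulatoryNetwork:
    """Convenience wrapper: intersect inputs, compute co-expression and
    run the message passing."""
    motif_a, ppi_a, coexpr = prepare_inputs(motif, ppi, expr)
    return panda(motif_a, ppi_a, coexpr, params)
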