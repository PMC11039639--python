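"""Differential network analysis: case-minus-control edge differences,
node targeting scores, per-TF significance and signed TF signatures.

Targeting follows the weighted-degree convention: a gene's targeting is
the sum of its incoming edge weights over all TFs (weighted in-degree),
a TF's targeting the sum of its outgoing edge weights over all genes
(weighted out-degree). On the differential network a positive targeting
difference means increased regulatory effect in cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DifferentialNetwork, RegulatoryNetwork, Signature

_EXACT_WILCOXON_MAX_N = 25


def _align(
    net_case: RegulatoryNetwork, net_control: RegulatoryNetwork
) -> tuple[pd.DataFrame, pd.DataFrame]:
    tfs = sorted(set(net_case.tf_names) & set(net_control.tf_names))
    genes = sorted(set(net_case.gene_names) & set(net_control.gene_names))
    if not tfs or not genes:
        raise ValueError("case and control networks share no TFs or no genes")
    return net_case.weights.loc[tfs, genes], net_control.weights.loc[tfs, genes]


def differential_network(
    net_case: RegulatoryNetwork, net_control: RegulatoryNetwork
) -> DifferentialNetwork:
    """Subtract control edge weights from case edge weights on the
    sorted TF/gene intersection and derive targeting scores."""
    case, control = _align(net_case, net_control)
    delta = case - control
    return DifferentialNetwork(
        delta=delta,
        gene_targeting=delta.sum(axis=0),
        tf_targeting=delta.sum(axis=1),
    )


def tf_significance(
    net_case: RegulatoryNetwork,
    net_control: RegulatoryNetwork,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-TF Wilcoxon signed-rank test of differential targeting.

    For each TF the paired samples are its case and control edge weights
    across the shared target genes. Zero differences are dropped
    (Wilcoxon's rule); the exact two-sided distribution is used for
    n <= 25 without ties in |difference|, otherwise the normal
    approximation with continuity correction. A Shapiro-Wilk p-value on
    the differences is reported as a normality diagnostic and p-values
    are Benjamini-Hochberg adjusted across all TFs.
    """
    case, control = _align(net_case, net_control)
    if case.shape[1] < 6:
        raise ValueError("need at least 6 shared genes for the signed-rank test")
    rows = []
    for tf in case.index:
        d = (case.loc[tf] - control.loc[tf]).to_numpy()
        dnz = d[d != 0]
        n = len(dnz)
        all_zero = n == 0
        if all_zero:
            statistic, p = np.nan, 1.0
        else:
            abs_ties = len(np.unique(np.abs(dnz))) < n
            method = "exact" if (n <= _EXACT_WILCOXON_MAX_N and not abs_ties) else "approx"
            res = stats.wilcoxon(
                dnz, zero_method="wilcox", correction=(method == "approx"),
                alternative="two-sided", method=method,
            )
            statistic, p = float(res.statistic), float(res.pvalue)
        if 3 <= n <= 5000:
            shapiro_p = float(stats.shapiro(dnz).pvalue)
        else:
            shapiro_p = np.nan
        total = float(d.sum())
        rows.append(
            {
                "tf": tf,
                "targeting_difference": total,
                "statistic": statistic,
                "p_value": p,
                "shapiro_p": shapiro_p,
                "n_nonzero": n,
                "all_zero": all_zero,
                "direction": "increased" if total > 0 else ("decreased" if total < 0 else "none"),
            }
        )
    result = pd.DataFrame(rows).set_index("tf")
    _, q, _, _ = multipletests(result["p_value"].to_numpy(), method="fdr_bh")
    result["q_value"] = q
    result["significant"] = result["q_value"] < alpha_fdr
    return result


def top_signature(
    diffnet: DifferentialNetwork, k: int = 100, name: str = "disease"
) -> Signature:
    """Signed TF signature of the differential network.

    The positive half holds up to ``k`` TFs with the largest positive
    differential targeting (descending), the negative half up to ``k``
    TFs with the most negative (ascending); zero-targeting TFs are never
    included and ties break lexicographically by TF name.
    """
    scores = diffnet.tf_targeting
    if (scores == 0).all():
        raise ValueError("no TF with nonzero differential targeting")
    pos = scores[scores > 0]
    neg = scores[scores < 0]
    pos_order = sorted(pos.index, key=lambda t: (-pos[t], t))[:k]
    neg_order = sorted(neg.index, key=lambda t: (neg[t], t))[:k]
    return Signature(name=name, positive=pos_order, negative=neg_order, k=k)


def ranked_gene_targeting(diffnet: DifferentialNetwork) -> pd.Series:
    """Gene targeting differences sorted descending — the ranking metric
    for enrichment analysis. Ties break lexicographically by gene name
    for determinism."""
    s = diffnet.gene_targeting
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]
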