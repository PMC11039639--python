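"""Signature-reversion drug matching.

A disease signature (TFs with increased targeting in the positive list,
decreased in the negative list) is compared against every drug signature
in a database by cosine similarity over signed indicator vectors: +1 at
positive members, -1 at negative members, 0 elsewhere. A perfect
reverser — a drug whose signature is the exact sign-flip of the disease
signature — scores -1; the more negative the cosine, the stronger the
predicted reversal. Significance uses a size-matched random-signature
null drawn from the TF vocabulary, one-sided toward reversal, with
Benjamini-Hochberg q-values across drugs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import DrugSignatureDB, Signature


def signature_vector(sig: Signature, vocabulary: list[str]) -> np.ndarray:
    """Signed indicator vector of a signature over a TF vocabulary.

    Members outside the vocabulary are a caller error: build the
    vocabulary as the union of all signatures involved.
    """
    index = {tf: i for i, tf in enumerate(vocabulary)}
    missing = [t for t in sig.members if t not in index]
    if missing:
        raise ValueError(f"signature members outside vocabulary: {missing[:5]}")
    vec = np.zeros(len(vocabulary))
    for tf in sig.positive:
        vec[index[tf]] = 1.0
    for tf in sig.negative:
        vec[index[tf]] = -1.0
    return vec


def cosine_score(disease: Signature, drug: Signature) -> float:
    """Cosine similarity of two signed signatures over their union
    vocabulary.

    Equals ``(|P∩P'| + |N∩N'| - |P∩N'| - |N∩P'|) /
    sqrt((|P|+|N|) (|P'|+|N'|))``; +1 for identical signatures, -1 for a
    perfect sign-flip.
    """
    if disease.is_empty() or drug.is_empty():
        raise ValueError("cosine similarity is undefined for an empty signature")
    dp_, dn = set(disease.positive), set(disease.negative)
    gp, gn = set(drug.positive), set(drug.negative)
    numerator = len(dp_ & gp) + len(dn & gn) - len(dp_ & gn) - len(dn & gp)
    # integer set arithmetic keeps antipodal/identical pairs exactly at -/+1
    denominator = math.sqrt((len(dp_) + len(dn)) * (len(gp) + len(gn)))
    return numerator / denominator


def _overlap_counts(disease: Signature, drug: Signature) -> dict[str, int]:
    dp, dn = set(disease.positive), set(disease.negative)
    gp, gn = set(drug.positive), set(drug.negative)
    return {
        "pos_pos": len(dp & gp),
        "pos_neg": len(dp & gn),
        "neg_pos": len(dn & gp),
        "neg_neg": len(dn & gn),
    }


def match_drugs(
    disease: Signature,
    db: DrugSignatureDB,
    n_null: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every drug in the database against a disease signature.

    The null distribution per drug reuses ``n_null`` random signatures
    with that drug's (positive, negative) sizes drawn without
    replacement from the vocabulary (cached per size class); the
    one-sided empirical p-value for reversal is ``P(null <= observed)``
    with add-one correction. Because the cosine of two finite signatures
    is a discrete statistic (an integer overlap count over a fixed
    denominator), ties with the null are broken by a seeded uniform
    draw — the classical randomised p-value construction that is exactly
    uniform under the null — and the result is floored at
    ``1/(n_null+1)``. Output is sorted ascending by cosine (most
    reversing first, drug name as tie-break).
    """
    if len(db) == 0:
        raise ValueError("drug database is empty")
    if disease.is_empty():
        raise ValueError("disease signature is empty")
    vocabulary = sorted(set(db.vocabulary) | set(disease.members))
    v = len(vocabulary)
    d_vec = signature_vector(disease, vocabulary)
    d_norm = np.linalg.norm(d_vec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5D]))

    null_cache: dict[tuple[int, int], np.ndarray] = {}

    def null_numerators(n_pos: int, n_neg: int) -> np.ndarray:
        key = (n_pos, n_neg)
        if key not in null_cache:
            m = n_pos + n_neg
            if m > v:
                raise ValueError(
                    f"vocabulary ({v} TFs) smaller than signature size {m}"
                )
            # n_null random signatures: first n_pos picks positive, rest negative
            picks = np.argsort(rng.random((n_null, v)), axis=1)[:, :m]
            signs = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
            null_cache[key] = (d_vec[picks] * signs[None, :]).sum(axis=1).round()
        return null_cache[key]

    rows = []
    dp_, dn = set(disease.positive), set(disease.negative)
    for name in sorted(db.drugs):
        drug = db.drugs[name]
        cos = cosine_score(disease, drug)
        gp, gn = set(drug.positive), set(drug.negative)
        numerator = len(dp_ & gp) + len(dn & gn) - len(dp_ & gn) - len(dn & gp)
        null = null_numerators(len(drug.positive), len(drug.negative))
        # integer comparison avoids float-equality artefacts in the tie count
        n_less = int(np.sum(null < numerator))
        n_tied = int(np.sum(null == numerator))
        u = rng.random()
        p = max((n_less + u * (n_tied + 1.0)) / (n_null + 1.0), 1.0 / (n_null + 1.0))
        rows.append({"drug": name, "cosine": cos, **_overlap_counts(disease, drug),
                     "p_value": p})
    result = pd.DataFrame(rows).set_index("drug")
    _, q, _, _ = multipletests(result["p_value"].to_numpy(), method="fdr_bh")
    result["q_value"] = q
    return result.sort_values(["cosine", "drug"], kind="stable")
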