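"""Synthetic study generator with planted ground truth.

Emulates the data a differential-regulatory-network study consumes:

* a sparse true TF -> gene regulatory strength matrix that differs
  between two diagnosis groups for a planted subset of TFs (rows
  amplified or attenuated by a known factor),
* negative-binomial RNA-seq counts driven by latent TF activities, with
  continuous (age-like) and categorical (batch-like) nuisance covariates,
* noisy motif and PPI priors derived from the true network,
* a drug-signature database containing planted "reversers" of the group
  difference among random decoys.

Every operation is deterministic given ``SimulationParams.seed``; a
single global seed expands into independent per-stage substreams so each
stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DrugSignatureDB, ExpressionMatrix, PPIMatrix, PriorNetwork, Signature

_STAGE_IDS = {"truth": 0, "counts": 1, "priors": 2, "drugs": 3}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study.

    Defaults are the toy scale the test-bed runs at: 30 TFs regulating
    200 genes, 50 case + 50 control samples, 3 TFs amplified and 3
    attenuated two-fold, 5% motif/PPI flip noise, and a 100-drug
    database with 5 planted reversers. ``expression_noise_sd`` of 1 sets
    unexplained log-scale variation comparable to a single TF's
    regulatory contribution, giving co-regulated gene correlations of
    roughly 0.2-0.45 in controls — strong but unsaturated modules, the
    regime where a two-fold regulatory change visibly moves
    co-expression.
    """

    n_tfs: int = 30
    n_genes: int = 200
    n_samples_per_group: int = 50
    n_perturbed_up: int = 3
    n_perturbed_down: int = 3
    effect_multiplier: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (500_000, 1_000_000)
    covariate_effect_sd: float = 0.3
    expression_noise_sd: float = 1.0
    prior_false_positive_rate: float = 0.05
    prior_false_negative_rate: float = 0.05
    n_drugs: int = 100
    n_reversers: int = 5
    drug_signature_noise: float = 0.2
    min_regulators: int = 1
    max_regulators: int = 3
    tf_activity_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tfs, self.n_genes, self.n_samples_per_group) <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_perturbed_up < 0 or self.n_perturbed_down < 0:
            raise ValueError("perturbed TF counts must be non-negative")
        if self.n_perturbed_up + self.n_perturbed_down > self.n_tfs:
            raise ValueError("more perturbed TFs than TFs")
        if self.effect_multiplier <= 1:
            raise ValueError("effect_multiplier must be > 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.covariate_effect_sd < 0:
            raise ValueError("covariate_effect_sd must be >= 0")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be >= 0")
        for rate in (self.prior_false_positive_rate, self.prior_false_negative_rate,
                     self.drug_signature_noise):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_reversers > self.n_drugs:
            raise ValueError("n_reversers exceeds n_drugs")
        if not 1 <= self.min_regulators <= self.max_regulators <= self.n_tfs:
            raise ValueError("regulator count range invalid")

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """Planted regulatory structure of the two diagnosis groups."""

    tf_names: list[str]
    gene_names: list[str]
    B_control: np.ndarray
    B_case: np.ndarray
    perturbed_tfs_up: set[str] = field(default_factory=set)
    perturbed_tfs_down: set[str] = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perturbed_tfs_up & self.perturbed_tfs_down:
            raise ValueError("a TF cannot be both amplified and attenuated")
        shape = (len(self.tf_names), len(self.gene_names))
        if self.B_control.shape != shape or self.B_case.shape != shape:
            raise ValueError("B matrices do not match tf/gene axes")

    def disease_signature(self, name: str = "disease-truth") -> Signature:
        """The planted perturbation as a signed TF signature
        (amplified TFs positive, attenuated TFs negative)."""
        return Signature(
            name=name,
            positive=sorted(self.perturbed_tfs_up),
            negative=sorted(self.perturbed_tfs_down),
        )


def _rng(params: SimulationParams, stage: str) -> np.random.Generator:
    """Per-stage substream of the global seed."""
    ss = np.random.SeedSequence([int(params.seed), _STAGE_IDS[stage]])
    return np.random.default_rng(ss)


def simulate_truth(params: SimulationParams) -> GroundTruth:
    """Draw the planted regulatory structure.

    Each gene is regulated by a small random TF subset with strengths
    drawn uniformly from [0.5, 1.5]; positive strengths make row
    amplification translate monotonically into stronger co-expression,
    the regime the downstream correlation evidence relies on. Case rows
    of amplified TFs are multiplied, attenuated rows divided, by
    ``effect_multiplier``.
    """
    rng = _rng(params, "truth")
    tf_names = [f"TF{i + 1:03d}" for i in range(params.n_tfs)]
    gene_names = [f"G{j + 1:04d}" for j in range(params.n_genes)]

    B = np.zeros((params.n_tfs, params.n_genes))
    for j in range(params.n_genes):
        k = rng.integers(params.min_regulators, params.max_regulators + 1)
        regulators = rng.choice(params.n_tfs, size=k, replace=False)
        B[regulators, j] = rng.uniform(0.5, 1.5, size=k)

    n_pert = params.n_perturbed_up + params.n_perturbed_down
    perturbed = rng.choice(params.n_tfs, size=n_pert, replace=False)
    up_idx = perturbed[: params.n_perturbed_up]
    down_idx = perturbed[params.n_perturbed_up:]

    B_case = B.copy()
    B_case[up_idx, :] *= params.effect_multiplier
    B_case[down_idx, :] /= params.effect_multiplier

    return GroundTruth(
        tf_names=tf_names,
        gene_names=gene_names,
        B_control=B,
        B_case=B_case,
        perturbed_tfs_up={tf_names[i] for i in up_idx},
        perturbed_tfs_down={tf_names[i] for i in down_idx},
        seed=params.seed,
    )


def simulate_counts(
    truth: GroundTruth, params: SimulationParams
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw two-group RNA-seq counts from the planted structure.

    Latent TF activities are standard normal per sample; gene log-means
    are ``baseline + B^T activity + covariate effects``, exponentiated
    and scaled to a sampled library size through a fixed normalising
    constant (a realised per-sample total would induce compositional
    correlations between unrelated genes); counts are negative binomial
    with dispersion ``nb_dispersion`` (variance mu + dispersion * mu^2). TF transcripts
    are appended as additional gene rows coupled to their own latent
    activity, so expression carries the TF's regulatory signal.

    Returns the counts matrix (target genes then TF transcripts, rows)
    and a covariate table with ``diagnosis``, a continuous ``age``, a
    categorical ``batch`` and a ``log_depth`` (log2 library size) column;
    the depth column plays the role of the QC covariates a real study
    regresses out, since raw counts carry a sample-wide depth offset.
    """
    if truth.B_control.shape != (params.n_tfs, params.n_genes):
        raise ValueError("truth and params axes do not match")
    rng = _rng(params, "counts")
    n_per = params.n_samples_per_group
    n_samples = 2 * n_per
    n_tfs, n_genes = params.n_tfs, params.n_genes
    n_rows = n_genes + n_tfs

    sample_names = [f"S{i + 1:03d}" for i in range(n_samples)]
    diagnosis = np.array(["control"] * n_per + ["case"] * n_per)
    age = rng.uniform(40.0, 90.0, size=n_samples)
    batch = rng.choice(["b1", "b2"], size=n_samples)

    baseline = rng.normal(0.0, 1.0, size=n_rows)
    # per-gene nuisance loadings
    age_load = rng.normal(0.0, 1.0, size=n_rows)
    batch_load = rng.normal(0.0, 1.0, size=n_rows)
    age_std = (age - age.mean()) / age.std()
    batch_ind = (batch == "b2").astype(float)

    activity = rng.normal(0.0, 1.0, size=(n_tfs, n_samples))
    noise = rng.normal(0.0, params.expression_noise_sd, size=(n_rows, n_samples))

    eta = np.empty((n_rows, n_samples))
    is_case = diagnosis == "case"
    eta[:n_genes, ~is_case] = truth.B_control.T @ activity[:, ~is_case]
    eta[:n_genes, is_case] = truth.B_case.T @ activity[:, is_case]
    eta[n_genes:, :] = params.tf_activity_coupling * activity
    eta += baseline[:, None] + noise
    eta += params.covariate_effect_sd * (
        age_load[:, None] * age_std[None, :] + batch_load[:, None] * batch_ind[None, :]
    )

    # scale by a fixed constant, not the realised per-sample total: a
    # per-sample softmax would induce compositional common-mode
    # correlations between all genes even with no regulation at all
    rel = np.exp(eta - eta.max())
    z = np.exp(baseline - eta.max()).sum()
    lib = rng.integers(params.library_size_range[0], params.library_size_range[1] + 1,
                       size=n_samples)
    mu = rel / z * lib[None, :]

    size = 1.0 / params.nb_dispersion  # NB shape: var = mu + mu^2 / size
    counts = rng.negative_binomial(size, size / (size + mu))

    row_names = list(truth.gene_names) + list(truth.tf_names)
    expr = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=row_names, columns=sample_names),
        kind="counts",
    )
    covariates = pd.DataFrame(
        {"diagnosis": diagnosis, "age": age, "batch": batch,
         "log_depth": np.log2(lib.astype(float))},
        index=sample_names,
    )
    covariates.index.name = "sample"
    return expr, covariates


def simulate_priors(
    truth: GroundTruth, params: SimulationParams
) -> tuple[PriorNetwork, PPIMatrix]:
    """Derive noisy motif and PPI priors from the true network.

    The motif prior is the binarised support of the control regulatory
    matrix with ones dropped at ``prior_false_negative_rate`` and zeros
    added at ``prior_false_positive_rate``. The PPI is 1 where two TFs
    share at least one true target, with symmetric flips at the same
    rates and a unit diagonal.
    """
    rng = _rng(params, "priors")
    support = (truth.B_control != 0).astype(float)

    flip_fn = rng.random(support.shape) < params.prior_false_negative_rate
    flip_fp = rng.random(support.shape) < params.prior_false_positive_rate
    motif = np.where(support == 1, np.where(flip_fn, 0.0, 1.0),
                     np.where(flip_fp, 1.0, 0.0))

    shared = (support @ support.T) > 0
    ppi = shared.astype(float)
    n = params.n_tfs
    iu = np.triu_indices(n, k=1)
    flips = rng.random(len(iu[0]))
    on = ppi[iu] == 1
    new_upper = ppi[iu].copy()
    new_upper[on & (flips < params.prior_false_negative_rate)] = 0.0
    new_upper[~on & (flips < params.prior_false_positive_rate)] = 1.0
    ppi[iu] = new_upper
    ppi.T[iu] = new_upper
    np.fill_diagonal(ppi, 1.0)

    motif_df = pd.DataFrame(motif, index=truth.tf_names, columns=truth.gene_names)
    ppi_df = pd.DataFrame(ppi, index=truth.tf_names, columns=truth.tf_names)
    return PriorNetwork(motif_df), PPIMatrix(ppi_df, threshold_applied=0.5)


def simulate_drug_db(
    truth: GroundTruth, params: SimulationParams
) -> tuple[DrugSignatureDB, set[str]]:
    """Build a drug-signature database with planted reversers.

    A reverser's signature is the sign-flip of the planted disease
    perturbation (positive list = attenuated TFs, negative list =
    amplified TFs) with a ``drug_signature_noise`` fraction of entries
    replaced by random other TFs; the first reverser is always exact so
    the database contains one noiseless reversal by construction. Decoys
    are random TF lists of the same sizes.
    """
    rng = _rng(params, "drugs")
    up = sorted(truth.perturbed_tfs_up)
    down = sorted(truth.perturbed_tfs_down)
    if params.n_reversers > 0 and not (up or down):
        raise ValueError("cannot plant reversers without a perturbation")

    all_tfs = list(truth.tf_names)
    n_pos, n_neg = len(down), len(up)
    if n_pos + n_neg == 0:  # unperturbed truth: decoys still need a size
        n_pos = n_neg = min(3, len(all_tfs) // 2)

    def _noisy(members: list[str], forbidden: set[str]) -> list[str]:
        members = list(members)
        n_replace = int(round(params.drug_signature_noise * len(members)))
        if n_replace == 0:
            return members
        idx = rng.choice(len(members), size=n_replace, replace=False)
        pool = [t for t in all_tfs if t not in forbidden]
        repl = rng.choice(pool, size=n_replace, replace=False)
        for i, r in zip(idx, repl):
            members[i] = str(r)
        return members

    def _random_signature(name: str) -> Signature:
        picked = rng.choice(all_tfs, size=min(n_pos + n_neg, len(all_tfs)), replace=False)
        return Signature(name=name, positive=[str(t) for t in picked[:n_pos]],
                         negative=[str(t) for t in picked[n_pos:]])

    drugs: dict[str, Signature] = {}
    planted: set[str] = set()
    for i in range(params.n_reversers):
        name = f"reverser{i + 1:02d}"
        if i == 0:
            sig = Signature(name=name, positive=list(down), negative=list(up))
        else:
            pos = _noisy(down, set(down) | set(up))
            neg = _noisy(up, set(pos) | set(up))
            sig = Signature(name=name, positive=pos, negative=neg)
        drugs[name] = sig
        planted.add(name)
    for i in range(params.n_drugs - params.n_reversers):
        name = f"decoy{i + 1:03d}"
        drugs[name] = _random_signature(name)

    metadata = {name: {"planted_reverser": name in planted} for name in drugs}
    return DrugSignatureDB(drugs=drugs, metadata=metadata), planted
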