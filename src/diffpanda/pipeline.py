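"""End-to-end orchestration: preprocess -> per-group PANDA ->
differential targeting -> enrichment -> drug repurposing.

``run_pipeline`` reads every input from disk, writes every intermediate
artifact into the output directory and finishes with a deterministic
JSON manifest (parameters, seeds, artifact checksums), so two runs with
the same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .containers import ExpressionMatrix, Signature
from .differential import (
    differential_network,
    ranked_gene_targeting,
    tf_significance,
    top_signature,
)
from .drug_match import match_drugs
from .enrichment import gsea
from .panda import PandaParams, panda, prepare_inputs
from .preprocess import collapse_duplicates, cpm_filter, log_transform, residualize
from .simulate import SimulationParams, simulate_counts, simulate_drug_db, simulate_priors, simulate_truth

logger = logging.getLogger("diffpanda")


@dataclass
class PipelineConfig:
    """Paths and stage parameters of a full run."""

    counts: str
    covariates: str
    motif: str
    ppi: str
    out_dir: str
    gmt: str | None = None
    drug_db: str | None = None
    case_level: str = "case"
    keep: str = "diagnosis"
    cpm_threshold: float = 0.5
    sample_fraction: float = 0.3
    ppi_threshold: float = 0.7
    alpha: float = 0.1
    tolerance: float = 0.001
    max_iter: int = 200
    k: int = 100
    n_perm: int = 1000
    min_size: int = 10
    max_size: int = 500
    n_null: int = 10_000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def validate(self) -> None:
        for name in ("counts", "covariates", "motif", "ppi"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"config {name}: no such file {path!r}")
        for name in ("gmt", "drug_db"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {name}: no such file {path!r}")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if not 0 <= self.ppi_threshold <= 1:
            raise ValueError("ppi_threshold must be in [0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage %s started", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the results bundle (in-memory
    objects plus the manifest). Stages with missing optional inputs
    (gene sets, drug database) are reported as skipped."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict = {"skipped": []}

    def _fail(stage: str, exc: Exception) -> Exception:
        inputs = {n: _sha256(Path(getattr(config, n)))[:12]
                  for n in ("counts", "covariates", "motif", "ppi")}
        return RuntimeError(f"stage {stage!r} failed (input checksums {inputs}): {exc}")

    # --- preprocess -------------------------------------------------------
    t0 = _stage("preprocess")
    try:
        expr = dio.read_expression_matrix(config.counts)
        covariates = dio.read_covariates(config.covariates)
        expr = collapse_duplicates(expr)
        expr = cpm_filter(expr, config.cpm_threshold, config.sample_fraction)
        expr = log_transform(expr)
        residuals = residualize(expr, covariates.loc[expr.sample_names], keep=config.keep)
    except Exception as exc:
        raise _fail("preprocess", exc) from exc
    dio.write_expression_matrix(residuals, out / "residuals.tsv")
    artifacts["residuals"] = out / "residuals.tsv"
    logger.info("stage preprocess done in %.2fs (%d genes kept)",
                time.perf_counter() - t0, residuals.n_genes)

    # --- per-group PANDA --------------------------------------------------
    t0 = _stage("panda")
    try:
        motif = dio.read_prior_edges(config.motif)
        ppi = dio.read_ppi_table(config.ppi, threshold=config.ppi_threshold)
        levels = sorted(covariates[config.keep].unique())
        if config.case_level not in levels:
            raise ValueError(f"case level {config.case_level!r} not among {levels}")
        control_level = next(l for l in levels if l != config.case_level)
        params = PandaParams(alpha=config.alpha, tolerance=config.tolerance,
                             max_iter=config.max_iter)
        # shared axes from the pooled expression, group-specific co-expression
        networks = {}
        for label, level in (("case", config.case_level), ("control", control_level)):
            samples = covariates.index[covariates[config.keep] == level]
            group_expr = ExpressionMatrix(
                residuals.values[[s for s in residuals.sample_names if s in set(samples)]],
                kind="residuals",
            )
            motif_a, ppi_a, coexpr = prepare_inputs(motif, ppi, group_expr)
            networks[label] = panda(motif_a, ppi_a, coexpr, params)
    except Exception as exc:
        raise _fail("panda", exc) from exc
    for label, net in networks.items():
        dio.write_network(net, out / f"network_{label}.tsv")
        artifacts[f"network_{label}"] = out / f"network_{label}.tsv"
    panda_report = {
        label: {"n_iterations": net.n_iterations, "converged": net.converged,
                "final_hamming": net.final_hamming}
        for label, net in networks.items()
    }
    (out / "panda_report.json").write_text(json.dumps(panda_report, indent=1))
    artifacts["panda_report"] = out / "panda_report.json"
    logger.info("stage panda done in %.2fs", time.perf_counter() - t0)

    # --- differential -----------------------------------------------------
    t0 = _stage("differential")
    try:
        diffnet = differential_network(networks["case"], networks["control"])
        tf_tests = tf_significance(networks["case"], networks["control"])
        signature = top_signature(diffnet, k=config.k)
    except Exception as exc:
        raise _fail("differential", exc) from exc
    dio.write_network(
        type(networks["case"])(weights=diffnet.delta), out / "differential_network.tsv"
    )
    tf_table = tf_tests.copy()
    tf_table.insert(0, "tf_targeting", diffnet.tf_targeting)
    tf_table.to_csv(out / "tf_targeting.tsv", sep="\t", float_format="%.17g")
    diffnet.gene_targeting.rename("gene_targeting").to_csv(
        out / "gene_targeting.tsv", sep="\t", float_format="%.17g"
    )
    dio.write_signature(signature, out / "signature.json")
    for key in ("differential_network", "tf_targeting", "gene_targeting"):
        artifacts[key] = out / f"{key}.tsv"
    artifacts["signature"] = out / "signature.json"
    results.update(diffnet=diffnet, tf_tests=tf_tests, signature=signature,
                   networks=networks)
    logger.info("stage differential done in %.2fs", time.perf_counter() - t0)

    # --- enrichment -------------------------------------------------------
    if config.gmt is not None:
        t0 = _stage("gsea")
        try:
            sets = dio.read_gmt(config.gmt)
            ranked = ranked_gene_targeting(diffnet)
            enrichment = gsea(ranked, sets, n_perm=config.n_perm,
                              min_size=config.min_size, max_size=config.max_size,
                              seed=config.seed)
        except Exception as exc:
            raise _fail("gsea", exc) from exc
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.17g")
        artifacts["enrichment"] = out / "enrichment.tsv"
        results["enrichment"] = enrichment
        logger.info("stage gsea done in %.2fs", time.perf_counter() - t0)
    else:
        results["skipped"].append("gsea")
        logger.info("stage gsea skipped (no gene-set collection)")

    # --- drug repurposing -------------------------------------------------
    if config.drug_db is not None:
        t0 = _stage("repurpose")
        try:
            db = dio.read_drug_db(config.drug_db)
            matches = match_drugs(signature, db, n_null=config.n_null, seed=config.seed)
        except Exception as exc:
            raise _fail("repurpose", exc) from exc
        matches.to_csv(out / "drug_matches.tsv", sep="\t", float_format="%.17g")
        artifacts["drug_matches"] = out / "drug_matches.tsv"
        results["drug_matches"] = matches
        logger.info("stage repurpose done in %.2fs", time.perf_counter() - t0)
    else:
        results["skipped"].append("repurpose")
        logger.info("stage repurpose skipped (no drug database)")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "parameters": {k: v for k, v in asdict(config).items() if k != "extra"},
        "seed": config.seed,
        "skipped": results["skipped"],
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results


def simulate_study(params: SimulationParams, out_dir: str | Path) -> dict:
    """Generate a full synthetic study and write it in the exact file
    formats the pipeline reads. Returns the ground truth and the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(params)
    expr, covariates = simulate_counts(truth, params)
    motif, ppi = simulate_priors(truth, params)
    db, planted = simulate_drug_db(truth, params)

    paths = {
        "counts": out / "counts.tsv",
        "covariates": out / "covariates.tsv",
        "motif": out / "motif.tsv",
        "ppi": out / "ppi.tsv",
        "drug_db_json": out / "drug_db.json",
        "drug_db_tsv": out / "drug_db.tsv",
    }
    dio.write_expression_matrix(expr, paths["counts"])
    dio.write_covariates(covariates, paths["covariates"])
    dio.write_prior_edges(motif, paths["motif"])
    dio.write_ppi_table(ppi, paths["ppi"])
    dio.write_drug_db(db, paths["drug_db_json"])
    dio.write_drug_db(db, paths["drug_db_tsv"])
    truth_record = {
        "perturbed_tfs_up": sorted(truth.perturbed_tfs_up),
        "perturbed_tfs_down": sorted(truth.perturbed_tfs_down),
        "planted_reversers": sorted(planted),
        "seed": params.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_record, indent=1))
    paths["truth"] = out / "truth.json"
    return {"truth": truth, "drug_db": db, "planted_reversers": planted, "paths": paths}
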