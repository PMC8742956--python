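"""End-to-end orchestration: preprocess → select → decompose → filter →
assign → hubs → associate, with every stage output written to disk.

`RunConfig` captures the whole run (paths, method/k overrides or "auto",
thresholds, permutation settings, seed) and round-trips losslessly through
YAML.  `run_pipeline` executes the stages in order, logs stage-tagged
warnings to stderr, and writes a manifest JSON naming every artifact so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .assign import ASSIGN_METHODS, detect_modules
from .association import module_trait_correlation
from .decomposition import DecompositionConfig, decompose
from .hubs import top_hub_genes
from .nongaussian import filter_signatures
from .preprocessing import drop_constant_genes, normalize_expression, remove_outlier_samples
from .selection import permutation_select_k, recommend_method

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("decomod")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run.

    ``method`` and ``k`` may be "auto", in which case the permutation
    selection stage chooses them; explicit values bypass it.  ``assign``
    is "auto" (FDR rule matching the decomposition) or one of ICA-FDR,
    ICA-Zscore, IPCA-FDR.
    """

    expression: str
    outdir: str
    clinical: str | None = None
    method: str = "auto"  # auto | ICA | IPCA
    k: int | str = "auto"  # auto | positive int
    assign: str = "auto"  # auto | ICA-FDR | ICA-Zscore | IPCA-FDR
    q: float = 0.001  # tail-FDR assignment threshold
    k_sigma: float = 3.0  # z-score assignment threshold
    kurtosis_threshold: float = 3.0
    z_cut: float = -2.5  # outlier-sample connectivity cut
    remove_outliers: bool = True
    drop_constant: bool = True
    impute_missing: bool = False
    k_max: int | None = None  # candidate cap for selection (default min(dims, 20))
    B: int = 50
    alpha: float = 0.05
    n_hub: int = 10
    seed: int = 0
    with_association: bool = True

    def validate(self) -> None:
        if self.method not in ("auto", "ICA", "IPCA"):
            raise ValueError(f"method must be auto/ICA/IPCA, got {self.method!r}")
        if self.assign not in ("auto",) + ASSIGN_METHODS:
            raise ValueError(f"assign must be auto or one of {ASSIGN_METHODS}")
        if self.method != "auto" and self.assign != "auto":
            required = "IPCA" if self.assign == "IPCA-FDR" else "ICA"
            if self.method != required:
                raise ValueError(
                    f"assignment rule {self.assign!r} requires method {required}, "
                    f"but method is {self.method!r}"
                )
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise ValueError(f"k must be 'auto' or a positive integer, got {self.k!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_assign(method: str, assign: str) -> str:
    if assign != "auto":
        return assign
    return "IPCA-FDR" if method == "IPCA" else "ICA-FDR"


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "config_digest": cfg.digest(),
        "stages": {},
        "warnings": [],
    }

    def record(stage: str, caught: list[warnings.WarningMessage]) -> None:
        for w in caught:
            msg = f"[{stage}] {w.message}"
            logger.warning(msg)
            manifest["warnings"].append(msg)

    # --- preprocess -------------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        X = io.read_expression(cfg.expression, impute_missing=cfg.impute_missing)
        if cfg.drop_constant:
            X, dropped_genes = drop_constant_genes(X)
        else:
            dropped_genes = []
        if cfg.remove_outliers:
            X, removed = remove_outlier_samples(X, cfg.z_cut)
        else:
            removed = []
        Xn = normalize_expression(X)
    record("preprocess", caught)
    io.write_expression(Xn, out / "normalized.tsv")
    manifest["stages"]["preprocess"] = {
        "output": "normalized.tsv",
        "n_genes": int(Xn.shape[0]),
        "n_samples": int(Xn.shape[1]),
        "removed_samples": removed,
        "dropped_constant_genes": dropped_genes,
    }

    # --- component selection ---------------------------------------------
    select_info: dict = {}
    if cfg.k == "auto":
        k_max = cfg.k_max or min(min(Xn.shape), 20)
        report = permutation_select_k(Xn, k_max=k_max, B=cfg.B, alpha=cfg.alpha, seed=cfg.seed)
        chosen_k = report.chosen_k
        if chosen_k == 0:
            raise RuntimeError(
                "component selection found no non-random structure (chosen_k = 0); "
                "the matrix is indistinguishable from row-permuted noise"
            )
        io.write_table(report.to_frame(), out / "selection.tsv", index_label="candidate_k")
        select_info["output"] = "selection.tsv"
    else:
        chosen_k = int(cfg.k)
        select_info["skipped_permutation"] = True
    method = cfg.method if cfg.method != "auto" else recommend_method(Xn, chosen_k, cfg.seed)
    select_info.update({"chosen_k": int(chosen_k), "method": method})
    manifest["stages"]["select"] = select_info

    assign_method = _resolve_assign(method, cfg.assign)
    if (method == "IPCA") != (assign_method == "IPCA-FDR"):
        raise ValueError(
            f"assignment rule {assign_method!r} is incompatible with the "
            f"selected decomposition method {method!r}"
        )

    # --- decomposition ----------------------------------------------------
    dconf = DecompositionConfig(method=method, n_components=chosen_k, seed=cfg.seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = decompose(Xn, dconf)
    record("decompose", caught)
    io.write_table(result.signatures, out / "signatures.tsv", index_label="gene_id")
    io.write_table(result.patterns, out / "patterns.tsv", index_label="component")
    io.write_json(result.to_manifest(), out / "decomposition.json")
    manifest["stages"]["decompose"] = {
        "outputs": ["signatures.tsv", "patterns.tsv", "decomposition.json"],
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
    }

    # --- kurtosis filter --------------------------------------------------
    filt = filter_signatures(result, cfg.kurtosis_threshold)
    io.write_table(filt.to_frame(), out / "signature_filter.tsv", index_label="signature")
    manifest["stages"]["filter"] = {
        "output": "signature_filter.tsv",
        "kept": [int(i + 1) for i in filt.kept_indices],
    }

    # --- module assignment ------------------------------------------------
    threshold = cfg.k_sigma if assign_method == "ICA-Zscore" else cfg.q
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        modules = detect_modules(result, filt, assign_method, threshold)
    record("detect", caught)
    io.write_table(modules.membership, out / "membership.tsv", index_label="gene_id")
    io.write_table(
        modules.to_long_frame().set_index("gene"), out / "membership_long.tsv", index_label="gene"
    )
    manifest["stages"]["detect"] = {
        "outputs": ["membership.tsv", "membership_long.tsv"],
        "method": assign_method,
        "threshold": threshold,
        "module_sizes": {m: int(n) for m, n in modules.sizes().items()},
    }

    # --- hub genes --------------------------------------------------------
    hubs = top_hub_genes(modules, cfg.n_hub)
    io.write_table(hubs.to_frame().set_index("module"), out / "hub_genes.tsv", index_label="module")
    manifest["stages"]["hubs"] = {"output": "hub_genes.tsv", "n_hub": cfg.n_hub}

    # --- association ------------------------------------------------------
    if cfg.with_association and cfg.clinical is not None:
        C = io.read_clinical(cfg.clinical)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assoc = module_trait_correlation(result, modules, C)
        record("associate", caught)
        io.write_table(
            assoc.to_frame().set_index("module"), out / "associations.tsv", index_label="module"
        )
        manifest["stages"]["associate"] = {"output": "associations.tsv"}
    else:
        manifest["stages"]["associate"] = {"skipped": True}

    cfg.to_yaml(out / "config.yaml")
    io.write_json(manifest, out / "manifest.json")
    return manifest
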