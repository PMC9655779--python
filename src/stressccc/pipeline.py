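"""End-to-end orchestration: simulate -> stratify -> preprocess -> de ->
enrich -> ccc, with a config, per-stage logging and a run manifest.

A run is driven by a :class:`RunConfig` (typically loaded from YAML)
whose keys surface every pipeline threshold under its standard default:
QC mito fraction < 0.15 and 200-2500 features, log-normalization scale
10,000, 2000 highly variable genes, DEG filter |logFC| > 0.25 with
BH-adjusted p < 0.05, min_pct 0.1, a 3-component GMM for behavioral
stratification.  Deterministic stages reproduce byte-identical outputs
for a fixed seed; the manifest records SHA-256 hashes of every output
file plus per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import assign_phenotype_gmm, assign_phenotype_threshold, compute_indices, fit_gmm, pca_with_loadings
from .ccc import edges_to_frame, run_ccc, write_lr_reference
from .diffexpr import deg_count_matrix, filter_degs, pooled_de, ranksum_de
from .enrichment import GeneSetCollection, hypergeom_enrich, top_terms
from .errors import ValidationError
from .io import sha256_file, write_cell_meta, write_gmt, write_mtx_triplet
from .preprocess import lognormalize, qc_filter, select_hvg
from .simulate import (
    GROUPS,
    REGIONS,
    BehaviorSimSpec,
    default_count_spec,
    generate_behavior,
    generate_counts,
    generate_lr_reference,
)

logger = logging.getLogger("stressccc")

STAGES = ("simulate", "stratify", "preprocess", "de", "enrich", "ccc")


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the standard defaults."""

    seed: int = 0
    out_dir: str = "results"
    stages: tuple = STAGES
    # synthetic data
    n_genes: int = 1000
    n_cells_per_stratum: int = 200
    fold_change: float = 3.0
    n_background_pairs: int = 100
    # thresholds
    mito_max: float = 0.15
    min_features: int = 200
    max_features: int = 2500
    scale: float = 10_000.0
    n_hvg: int = 2000
    min_pct: float = 0.1
    lfc_min: float = 0.25
    alpha: float = 0.05
    gmm_k: int = 3
    gmm_starts: int = 20
    extreme_low: float = 0.75
    extreme_high: float = 1.15
    n_background_terms: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.mito_max <= 1:
            raise ValidationError("mito_max must be in (0, 1]")
        if self.min_features > self.max_features:
            raise ValidationError("min_features exceeds max_features")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        deps = {"ccc": "de", "enrich": "de", "de": "preprocess",
                "preprocess": "simulate", "stratify": "simulate"}
        for stage, dep in deps.items():
            if stage in self.stages and dep not in self.stages:
                raise ValidationError(
                    f"stage {stage!r} requires stage {dep!r} to be enabled"
                )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def run_all(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order on default synthetic data.

    Fails fast with stage-scoped errors; writes every table under
    ``config.out_dir`` and returns the manifest (also written as
    ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), version=__version__
    )

    def record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = sha256_file(path)

    rng = np.random.default_rng(config.seed)

    # --- simulate -----------------------------------------------------
    behavior = counts = truth = ref = None
    if "simulate" in config.stages:
        logger.info("stage simulate")
        behavior = generate_behavior(BehaviorSimSpec(seed=config.seed))
        spec = default_count_spec(
            seed=config.seed + 1,
            n_genes=config.n_genes,
            n_cells_per_stratum=config.n_cells_per_stratum,
            fold_change=config.fold_change,
        )
        counts, truth = generate_counts(spec)
        planted_pairs = [(e.ligand, e.receptor) for e in truth.lr_edges]
        # background pairs live on genes without planted effects, so any
        # edge they generate is a genuine false positive
        unplanted = [
            g for g in counts.gene_ids if g not in set(truth.degs["gene"])
        ]
        ref = generate_lr_reference(
            config.n_background_pairs,
            planted_pairs,
            seed=config.seed + 2,
            gene_pool=unplanted,
        )
        behavior.to_csv(out / "behavior.csv", index=False)
        write_mtx_triplet(out / "counts", counts.counts, counts.gene_ids,
                          counts.barcodes)
        write_cell_meta(out / "cell_meta.csv", counts.cell_meta)
        truth.degs.to_csv(out / "truth_degs.tsv", sep="\t", index=False)
        edges_to_frame(truth.lr_edges).to_csv(
            out / "truth_lr_edges.tsv", sep="\t", index=False
        )
        write_lr_reference(out / "lr_reference.tsv", ref)
        for f in ("behavior.csv", "cell_meta.csv", "truth_degs.tsv",
                  "truth_lr_edges.tsv", "lr_reference.tsv",
                  "counts/matrix.mtx", "counts/features.tsv",
                  "counts/barcodes.tsv"):
            record(out / f)
        manifest.counts["simulate"] = {
            "mice": len(behavior),
            "cells": counts.n_cells,
            "genes": counts.n_genes,
            "lr_pairs": len(ref),
        }

    # --- stratify -----------------------------------------------------
    if "stratify" in config.stages:
        logger.info("stage stratify")
        defeated = behavior[behavior["condition"] == "defeated"]
        fit = fit_gmm(
            defeated["si_index"].to_numpy(),
            k=config.gmm_k,
            n_starts=config.gmm_starts,
            seed=config.seed,
        )
        assign = assign_phenotype_gmm(fit, defeated["si_index"].to_numpy())
        pheno = pd.DataFrame(
            {
                "id": defeated["id"].to_numpy(),
                "si_index": defeated["si_index"].to_numpy(),
                "msi_cd1": defeated["msi_cd1"].to_numpy(),
                "msi_129": defeated["msi_129"].to_numpy(),
                "label_gmm": assign["label"].to_numpy(),
                "label_threshold": [
                    assign_phenotype_threshold(s) for s in defeated["si_index"]
                ],
            }
        )
        pheno.to_csv(out / "phenotypes.csv", index=False)
        pca = pca_with_loadings(
            compute_indices(behavior)[["si_index", "msi_cd1", "msi_129"]]
        )
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        for f in ("phenotypes.csv", "pca_scores.tsv", "pca_loadings.tsv"):
            record(out / f)
        manifest.counts["stratify"] = {
            "defeated": len(pheno),
            "gmm_iterations": fit.n_iter,
            "gmm_converged": bool(fit.converged),
        }

    # --- preprocess ---------------------------------------------------
    norm = None
    if "preprocess" in config.stages:
        logger.info("stage preprocess")
        filtered, report = qc_filter(
            counts,
            mito_max=config.mito_max,
            min_features=config.min_features,
            max_features=config.max_features,
        )
        report.to_csv(out / "qc_report.csv")
        norm = lognormalize(filtered, scale=config.scale)
        hvg = select_hvg(norm, n_top=min(config.n_hvg, norm.n_genes))
        pd.Series(hvg, name="gene").to_csv(out / "hvg.tsv", sep="\t",
                                           index=False)
        for f in ("qc_report.csv", "hvg.tsv"):
            record(out / f)
        manifest.counts["preprocess"] = {
            "cells_in": counts.n_cells,
            "cells_kept": filtered.n_cells,
            "removed_mito": int((~report["pass_mito"]).sum()),
            "removed_features": int((~report["pass_features"]).sum()),
            "hvg": len(hvg),
        }

    # --- differential expression ---------------------------------------
    de_filtered: dict = {}
    if "de" in config.stages:
        logger.info("stage de")
        meta = norm.cell_meta
        all_tables = []
        for group in [g for g in GROUPS if g != "control"]:
            for region in REGIONS:
                de_filtered[(group, region)] = {}
                for ctype in sorted(meta["cell_type"].unique()):
                    test = (
                        (meta["group"] == group)
                        & (meta["region"] == region)
                        & (meta["cell_type"] == ctype)
                    ).to_numpy()
                    ctrl = (
                        (meta["group"] == "control")
                        & (meta["region"] == region)
                        & (meta["cell_type"] == ctype)
                    ).to_numpy()
                    table = ranksum_de(norm, test, ctrl, min_pct=config.min_pct)
                    table["group"] = group
                    table["region"] = region
                    table["cell_type"] = ctype
                    all_tables.append(table)
                    de_filtered[(group, region)][ctype] = filter_degs(
                        table, lfc_min=config.lfc_min, alpha=config.alpha
                    )
                pooled = pooled_de(norm, group, region, min_pct=config.min_pct)
                pooled["group"] = group
                pooled["cell_type"] = "pooled"
                all_tables.append(pooled)
        de_all = pd.concat(all_tables, ignore_index=True)
        de_all.to_csv(out / "de_tables.tsv", sep="\t", index=False)
        count_mat = deg_count_matrix(
            {
                (ct, region, f"{group}_vs_control"): tab
                for (group, region), per_type in de_filtered.items()
                for ct, tab in per_type.items()
            }
        )
        count_mat.to_csv(out / "deg_counts.csv", index=False)
        for f in ("de_tables.tsv", "deg_counts.csv"):
            record(out / f)
        manifest.counts["de"] = {
            "comparisons": int(len(count_mat)),
            "filtered_degs": int(count_mat["n_degs"].sum()),
        }

    # --- enrichment ---------------------------------------------------
    if "enrich" in config.stages:
        logger.info("stage enrich")
        universe = list(norm.gene_ids)
        planted_term = sorted(set(truth.degs["gene"]))
        terms = {"PLANTED": ("planted Int-dorsal program", frozenset(planted_term))}
        for i in range(config.n_background_terms):
            size = int(rng.integers(10, 50))
            genes = rng.choice(universe, size=size, replace=False)
            terms[f"BG{i + 1:03d}"] = (f"background set {i + 1}", frozenset(genes))
        write_gmt(out / "genesets.gmt", terms)
        coll = GeneSetCollection(terms=terms, universe=frozenset(universe))
        int_dorsal_degs = set()
        for tab in de_filtered.get(("Int", "dorsal"), {}).values():
            int_dorsal_degs |= set(tab["gene"])
        if int_dorsal_degs:
            enr = hypergeom_enrich(int_dorsal_degs, coll)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            top_terms(enr, 10).to_csv(out / "enrichment_top10.tsv", sep="\t",
                                      index=False)
            record(out / "enrichment.tsv")
            record(out / "enrichment_top10.tsv")
            manifest.counts["enrich"] = {
                "query": len(int_dorsal_degs),
                "terms": len(terms),
            }
        else:
            logger.warning("no Int-dorsal DEGs; enrichment skipped")
            manifest.counts["enrich"] = {"query": 0, "terms": len(terms)}
        record(out / "genesets.gmt")

    # --- ligand-receptor network ---------------------------------------
    if "ccc" in config.stages:
        logger.info("stage ccc")
        edge_frames = []
        summary_rows = []
        for stratum in de_filtered:
            edges, summary = run_ccc(de_filtered, ref, stratum)
            frame = edges_to_frame(edges)
            frame.insert(0, "region", stratum[1])
            frame.insert(0, "group", stratum[0])
            edge_frames.append(frame)
            summary_rows.append(
                {
                    "group": stratum[0],
                    "region": stratum[1],
                    "n_edges": summary.n_edges,
                    "unique_pairs": summary.unique_pair_count,
                }
            )
        pd.concat(edge_frames, ignore_index=True).to_csv(
            out / "ccc_edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(summary_rows).to_csv(out / "ccc_summary.csv", index=False)
        for f in ("ccc_edges.tsv", "ccc_summary.csv"):
            record(out / f)
        manifest.counts["ccc"] = {
            r["group"] + ":" + r["region"]: r["n_edges"] for r in summary_rows
        }

    manifest.write(out / "manifest.json")
    return manifest
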