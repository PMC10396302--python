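"""End-to-end pipeline: config handling and the `run_all` stage chain.

Stages: QC -> normalize -> variable genes -> PCA -> initial clusters (or
external labels) -> merge -> markers -> TAI + enrichment, optionally
followed by cross-species alignment (when a second species is configured)
and the neuropeptide scan (when a proteome is configured). Outputs are
written incrementally as TSV; a resolved copy of the configuration is
written next to them, and identical config + inputs reproduce identical
bytes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import (
    agemix,
    cluster_merge,
    crossalign,
    io_core,
    np_scan,
    preprocess,
)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_all"]

SCHEMA_VERSION = 1

_SCHEMA: dict[str, set[str]] = {
    "": {
        "schema_version", "seed", "out_dir", "input", "qc", "normalize",
        "variable_genes", "pca", "clustering", "merge", "markers", "ages",
        "species_b", "ortholog_map", "align", "proteome", "signal_calls",
        "npscan",
    },
    "input": {"matrix", "barcodes", "features", "mito_prefix", "external_labels"},
    "qc": {"min_genes_per_cell", "max_mito_fraction", "umi_bound", "umi_bound_side"},
    "normalize": {"scale"},
    "variable_genes": {"n"},
    "pca": {"d", "clip"},
    "clustering": {"resolution", "k_neighbors"},
    "merge": {"de_gene_threshold", "p_threshold", "min_abs_log2fc"},
    "markers": {"p_threshold", "min_log2fc"},
    "species_b": {"matrix", "barcodes", "features", "mito_prefix", "external_labels"},
    "align": {"k", "d", "prune_below"},
    "npscan": {"min_peptides", "min_len", "max_len"},
}


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_keys(section: str, mapping: dict, schema_key: str) -> None:
    unknown = set(mapping) - _SCHEMA[schema_key]
    if unknown:
        where = section or "top level"
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (every parameter explicit)."""

    seed: int
    out_dir: str
    input: dict[str, Any]
    qc: dict[str, Any]
    normalize: dict[str, Any]
    variable_genes: dict[str, Any]
    pca: dict[str, Any]
    clustering: dict[str, Any]
    merge: dict[str, Any]
    markers: dict[str, Any]
    ages: str | None = None
    species_b: dict[str, Any] | None = None
    ortholog_map: str | None = None
    align: dict[str, Any] = field(default_factory=dict)
    proteome: str | None = None
    signal_calls: str | None = None
    npscan: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a mapping")
        _check_keys("", raw, "")
        version = raw.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ConfigError(
                f"schema_version must be {SCHEMA_VERSION}, got {version!r}"
            )
        if "input" not in raw or "out_dir" not in raw:
            raise ConfigError("config needs 'input' and 'out_dir'")

        def section(name: str, defaults: dict) -> dict:
            got = raw.get(name) or {}
            _check_keys(name, got, name)
            return {**defaults, **got}

        input_cfg = section(
            "input",
            {"matrix": None, "barcodes": None, "features": None,
             "mito_prefix": "mt-", "external_labels": None},
        )
        for key in ("matrix", "barcodes", "features"):
            if not input_cfg.get(key):
                raise ConfigError(f"input.{key} is required")
        species_b = None
        if raw.get("species_b"):
            _check_keys("species_b", raw["species_b"], "species_b")
            species_b = {
                "mito_prefix": "mt-", "external_labels": None,
                **raw["species_b"],
            }
            for key in ("matrix", "barcodes", "features"):
                if not species_b.get(key):
                    raise ConfigError(f"species_b.{key} is required")
            if not raw.get("ortholog_map"):
                raise ConfigError("species_b requires ortholog_map")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw["out_dir"]),
            input=input_cfg,
            qc=section("qc", {
                "min_genes_per_cell": 200, "max_mito_fraction": 0.20,
                "umi_bound": 5000, "umi_bound_side": "upper",
            }),
            normalize=section("normalize", {"scale": 10000.0}),
            variable_genes=section("variable_genes", {"n": 2000}),
            pca=section("pca", {"d": 70, "clip": 10.0}),
            clustering=section("clustering", {"resolution": 10.0, "k_neighbors": 20}),
            merge=section("merge", {
                "de_gene_threshold": 20, "p_threshold": 0.01,
                "min_abs_log2fc": 0.25,
            }),
            markers=section("markers", {"p_threshold": 0.05, "min_log2fc": 0.25}),
            ages=raw.get("ages"),
            species_b=species_b,
            ortholog_map=raw.get("ortholog_map"),
            align=section("align", {"k": 20, "d": 30, "prune_below": 0.1}),
            proteome=raw.get("proteome"),
            signal_calls=raw.get("signal_calls"),
            npscan=section("npscan", {"min_peptides": 2, "min_len": 3, "max_len": 40}),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        out = {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input": self.input,
            "qc": self.qc,
            "normalize": self.normalize,
            "variable_genes": self.variable_genes,
            "pca": self.pca,
            "clustering": self.clustering,
            "merge": self.merge,
            "markers": self.markers,
            "ages": self.ages,
            "species_b": self.species_b,
            "ortholog_map": self.ortholog_map,
            "align": self.align,
            "proteome": self.proteome,
            "signal_calls": self.signal_calls,
            "npscan": self.npscan,
        }
        return out

    def check_inputs(self) -> None:
        """Fail before any compute when an enabled stage's inputs are missing."""
        paths = [self.input["matrix"], self.input["barcodes"], self.input["features"]]
        if self.input.get("external_labels"):
            paths.append(self.input["external_labels"])
        if self.ages:
            paths.append(self.ages)
        if self.species_b:
            paths += [
                self.species_b["matrix"], self.species_b["barcodes"],
                self.species_b["features"], self.ortholog_map,
            ]
            if self.species_b.get("external_labels"):
                paths.append(self.species_b["external_labels"])
        if self.proteome:
            paths.append(self.proteome)
        if self.signal_calls:
            paths.append(self.signal_calls)
        missing = [p for p in paths if p and not os.path.exists(p)]
        if missing:
            raise ConfigError(f"missing input file(s): {missing}")


def _process_species(
    cfg: PipelineConfig,
    source: dict[str, Any],
    out_dir: str,
    tag: str,
    log: list[str],
) -> tuple[io_core.ExpressionMatrix, io_core.ClusterLabels]:
    """QC, normalize, cluster (or adopt external labels), and merge one dataset."""
    prefix = f"{tag}_" if tag else ""

    def stage(name: str):
        log.append(f"{prefix}{name}")

    stage("qc")
    cm = io_core.read_mtx_bundle(
        source["matrix"], source["barcodes"], source["features"],
        mito_prefix=source.get("mito_prefix", "mt-"),
    )
    qc = preprocess.QCParams(**cfg.qc)
    cm, report = preprocess.filter_cells(cm, qc)
    pd.DataFrame([report.summary()]).pipe(
        io_core.write_tsv_table, os.path.join(out_dir, f"{prefix}qc_report.tsv")
    )
    with open(os.path.join(out_dir, f"{prefix}qc_summary.json"), "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    stage("normalize")
    em = preprocess.normalize_log1p(cm, scale=cfg.normalize["scale"])

    if source.get("external_labels"):
        stage("external_labels")
        labels = io_core.read_labels(source["external_labels"])
    else:
        stage("variable_genes")
        hvg = preprocess.select_variable_genes(cm, n=cfg.variable_genes["n"])
        stage("pca")
        d = min(cfg.pca["d"], cm.n_cells, len(hvg))
        emb = preprocess.embed_pca(em, hvg, d=d, clip=cfg.pca["clip"])
        stage("initial_clusters")
        labels = preprocess.initial_clusters(
            emb,
            resolution=cfg.clustering["resolution"],
            k_neighbors=cfg.clustering["k_neighbors"],
            seed=cfg.seed,
        )
    io_core.write_labels(labels, os.path.join(out_dir, f"{prefix}labels_initial.tsv"))

    stage("merge")
    params = cluster_merge.MergeParams(**cfg.merge)
    merged = cluster_merge.merge_iterate(em, labels, params)
    io_core.write_labels(merged, os.path.join(out_dir, f"{prefix}labels_merged.tsv"))
    io_core.write_tsv_table(
        cluster_merge.merge_log_table(merged),
        os.path.join(out_dir, f"{prefix}merge_log.tsv"),
    )
    return em, merged


def run_all(config: PipelineConfig) -> str:
    """Execute every enabled stage; returns the result directory.

    A stage failure raises :class:`StageError` naming the failing stage;
    inputs for enabled stages are checked before any compute.
    """
    config.check_inputs()
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    log: list[str] = []

    def run_stage(name: str, fn, *args, **kwargs):
        log.append(name)
        try:
            return fn(*args, **kwargs)
        except (ConfigError, StageError):
            raise
        except Exception as exc:  # noqa: BLE001 - named stage failure contract
            raise StageError(name, exc) from exc

    try:
        em, merged = _process_species(config, config.input, out_dir, "", log)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(log[-1] if log else "qc", exc) from exc

    markers = run_stage(
        "markers",
        agemix.find_markers,
        em,
        merged,
        p_threshold=config.markers["p_threshold"],
        min_log2fc=config.markers["min_log2fc"],
    )
    marker_rows = [
        {"cluster_id": cid, **row}
        for cid, tab in sorted(markers.per_cluster.items())
        for row in tab.to_dict("records")
    ]
    io_core.write_tsv_table(
        pd.DataFrame(marker_rows, columns=["cluster_id", "gene_id", "adjusted_p", "log2fc"]),
        os.path.join(out_dir, "markers.tsv"),
    )

    if config.ages:
        def tai_stage():
            ages = io_core.read_gene_ages(config.ages)
            tai = agemix.tai_profile(em, merged, ages)
            io_core.write_tsv_table(tai, os.path.join(out_dir, "tai.tsv"))
            expressed = [
                g for g, pos in zip(
                    em.gene_ids, (em.values > 0).any(axis=0)
                ) if pos
            ]
            grid = agemix.phylostratum_enrichment(markers, ages, expressed)
            io_core.write_tsv_table(grid, os.path.join(out_dir, "enrichment.tsv"))

        run_stage("tai_enrichment", tai_stage)
    else:
        log.append("tai_enrichment: skipped (no ages configured)")

    if config.species_b:
        def align_stage():
            em_b, merged_b = _process_species(
                config, config.species_b, out_dir, "b", log
            )
            omap = io_core.read_ortholog_map(config.ortholog_map)
            mat_a, mat_b, _info = crossalign.collapse_to_ortholog_space(
                em, em_b, omap
            )
            d = min(config.align["d"], mat_a.n_genes, mat_a.n_cells + mat_b.n_cells)
            joint = crossalign.joint_embedding(mat_a, mat_b, d=d)
            pairs = crossalign.mutual_nn(joint, k=config.align["k"])
            full, pruned = crossalign.alignment_scores(
                pairs, merged, merged_b, k=config.align["k"],
                prune_below=config.align["prune_below"],
            )
            full.rename_axis("cluster_a").reset_index().pipe(
                io_core.write_tsv_table, os.path.join(out_dir, "alignment_full.tsv")
            )
            pruned.rename_axis("cluster_a").reset_index().pipe(
                io_core.write_tsv_table, os.path.join(out_dir, "alignment_pruned.tsv")
            )
            io_core.write_tsv_table(
                pd.DataFrame(sorted(pairs), columns=["cell_a", "cell_b"]),
                os.path.join(out_dir, "mutual_pairs.tsv"),
            )

        run_stage("align", align_stage)
    else:
        log.append("align: skipped (no species_b configured)")

    if config.proteome:
        def npscan_stage():
            proteins = io_core.read_fasta(config.proteome)
            calls = (
                np_scan.read_signal_calls(config.signal_calls)
                if config.signal_calls
                else None
            )
            cands = np_scan.scan_proteome(
                proteins,
                calls,
                min_len=config.npscan["min_len"],
                max_len=config.npscan["max_len"],
            )
            report = np_scan.rank_candidates(
                cands, min_peptides=config.npscan["min_peptides"]
            )
            io_core.write_tsv_table(
                report, os.path.join(out_dir, "np_candidates.tsv")
            )
            pep_rows = [
                {
                    "protein_id": c.protein_id,
                    "start": p.start,
                    "end": p.end,
                    "sequence": p.sequence,
                    "amidated": int(p.amidated),
                }
                for c in cands
                for p in c.peptides
            ]
            io_core.write_tsv_table(
                pd.DataFrame(
                    pep_rows,
                    columns=["protein_id", "start", "end", "sequence", "amidated"],
                ),
                os.path.join(out_dir, "np_peptides.tsv"),
            )

        run_stage("npscan", npscan_stage)
    else:
        log.append("npscan: skipped (no proteome configured)")

    with open(os.path.join(out_dir, "stage_log.txt"), "w") as fh:
        fh.writelines(line + "\n" for line in log)
    return out_dir
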