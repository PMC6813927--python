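"""End-to-end orchestration: preprocess -> network -> traits -> enrichment
-> homeolog bias -> guide subnetworks, with a reproducible report.

The configuration is a flat key/value structure (YAML on disk) serialized
verbatim into the report; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import enrich, homeolog, preprocess, subnet, traits
from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    HomeologTable,
    SampleTable,
    read_expression_tsv,
    read_gene_sets,
    read_homeolog_table,
    read_sample_table,
)
from .network import CoexpressionNetwork, CoexpressionResults

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger("triadnet")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of a pipeline run."""

    tpm_path: str = ""
    counts_path: str = ""
    samples_path: str = ""
    homeologs_path: str = ""
    gene_sets_path: str = ""
    output_dir: str = "triadnet_out"
    target_tissue: str = "meiotic_anther"
    tpm_threshold: float = 0.5
    powers: tuple[int, ...] = tuple(range(1, 21))
    target_fit: float = 0.9
    beta: int | None = None
    network_type: str = "signed_hybrid"
    max_p_outliers: float = 0.05
    min_module_size: int = 30
    merge_cut_height: float = 0.15
    cut_height: float = 0.99
    r_high: float = 0.5
    r_low: float = 0.3
    fdr_max: float = 0.05
    subnet_weight_min: float = 0.05
    n_hub_genes: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.tpm_threshold < 0 or self.max_p_outliers < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0 <= self.subnet_weight_min < 1:
            raise ValueError("subnet_weight_min must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if "powers" in data:
            data["powers"] = tuple(int(p) for p in data["powers"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        out = dict(self.__dict__)
        out["powers"] = list(self.powers)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineReport:
    config: PipelineConfig
    summary: dict[str, Any]
    results: CoexpressionResults
    trait_table: pd.DataFrame
    selected_modules: list[int]
    enrichment: list[enrich.EnrichmentResult] = field(default_factory=list)
    triad_categories: dict[str, list[homeolog.TriadContribution]] = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = [self.results.summary(), ""]
        lines.append(f"selected {self.config.target_tissue} modules: "
                     f"{self.selected_modules or 'none'}")
        for key, value in self.summary.items():
            lines.append(f"{key}: {value}")
        return "\n".join(lines)


def _header(config: PipelineConfig) -> str:
    return f"# triadnet 0.1.0 config={config.config_hash()}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, **kwargs) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_header(config))
        frame.to_csv(handle, sep="\t", **kwargs)


def run_pipeline(
    config: PipelineConfig,
    *,
    tpm: ExpressionMatrix | None = None,
    counts: ExpressionMatrix | None = None,
    samples: SampleTable | None = None,
    homeologs: HomeologTable | None = None,
    gene_sets: GeneSetCollection | None = None,
    write_outputs: bool = True,
) -> PipelineReport:
    """Run every stage and write the report bundle.

    Inputs may be passed in memory; any not provided are read from the
    configured paths.  Stage failures abort with a stage-tagged message.
    """
    config.validate()
    outdir = Path(config.output_dir)

    def stage(name: str):
        logger.info("stage %s", name)

    try:
        stage("load")
        if tpm is None:
            tpm = read_expression_tsv(config.tpm_path, unit="TPM")
        if counts is None:
            counts = read_expression_tsv(config.counts_path, unit="count")
        if samples is None:
            samples = read_sample_table(config.samples_path)
        if homeologs is None and config.homeologs_path:
            homeologs = read_homeolog_table(config.homeologs_path)
        if gene_sets is None and config.gene_sets_path:
            gene_sets = read_gene_sets(config.gene_sets_path)
    except Exception as err:
        raise RuntimeError(f"[load] {err}") from err

    try:
        stage("preprocess")
        target_samples = samples.samples_of(config.target_tissue)
        filt = preprocess.filter_expressed(tpm, target_samples, config.tpm_threshold)
        counts_kept = counts.subset_genes(filt.kept_gene_ids)
        factors = preprocess.size_factors(counts_kept)
        normed = preprocess.normalize(counts_kept, factors)
        logger.info("kept %d of %d genes", filt.n_kept, tpm.n_genes)
    except Exception as err:
        raise RuntimeError(f"[preprocess] {err}") from err

    try:
        stage("network")
        model = CoexpressionNetwork(
            normed,
            network_type=config.network_type,
            max_p_outliers=config.max_p_outliers,
        )
        results = model.fit(
            beta=config.beta,
            powers=config.powers,
            target_fit=config.target_fit,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
            cut_height=config.cut_height,
        )
    except Exception as err:
        raise RuntimeError(f"[network] {err}") from err

    try:
        stage("traits")
        indicators = traits.tissue_indicators(samples)
        trait_table = traits.module_trait_correlation(results.eigengenes, indicators)
        selected = traits.select_meiosis_modules(
            trait_table,
            config.target_tissue,
            r_high=config.r_high,
            r_low=config.r_low,
            fdr_max=config.fdr_max,
        )
    except Exception as err:
        raise RuntimeError(f"[traits] {err}") from err

    enrichment: list[enrich.EnrichmentResult] = []
    if gene_sets:
        try:
            stage("enrich")
            background = [g for g, m in results.partition.items() if m != 0]
            for name, members in gene_sets.items():
                if not set(members) & set(background):
                    logger.warning("gene set %r does not meet the background; skipped", name)
                    continue
                enrichment.extend(
                    enrich.set_enrichment(
                        results.partition, members, background, set_name=name
                    )
                )
        except Exception as err:
            raise RuntimeError(f"[enrich] {err}") from err

    triad_categories: dict[str, list[homeolog.TriadContribution]] = {}
    if homeologs is not None:
        try:
            stage("homeolog")
            triad_categories[config.target_tissue] = homeolog.classify_triads_in_tissue(
                tpm, samples, homeologs, config.target_tissue
            )
        except Exception as err:
            raise RuntimeError(f"[homeolog] {err}") from err

    sizes = results.module_sizes()
    summary: dict[str, Any] = {
        "n_genes_input": tpm.n_genes,
        "n_genes_expressed": filt.n_kept,
        "n_modules": int(len(sizes)),
        "n_assigned": results.partition.n_assigned,
        "percent_assigned": round(results.percent_assigned, 1),
        "module_size_mean": round(float(sizes.mean()), 1) if len(sizes) else 0.0,
        "module_size_median": float(sizes.median()) if len(sizes) else 0.0,
        "beta": results.params["beta"],
        "selected_modules": selected,
    }
    if triad_categories.get(config.target_tissue):
        cats = [t.category for t in triad_categories[config.target_tissue]]
        summary["n_triads_classified"] = len(cats)
        summary["percent_balanced_triads"] = round(
            100.0 * sum(c == "balanced" for c in cats) / len(cats), 1
        )

    report = PipelineReport(
        config=config,
        summary=summary,
        results=results,
        trait_table=trait_table,
        selected_modules=selected,
        enrichment=enrichment,
        triad_categories=triad_categories,
    )

    if write_outputs:
        stage("write")
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            results.partition.labels.rename("module").to_frame(),
            outdir / "modules.tsv",
            config,
            index_label="gene_id",
        )
        _write_tsv(results.eigengenes.values, outdir / "eigengenes.tsv", config,
                   index_label="module")
        _write_tsv(results.kme, outdir / "kme.tsv", config, index_label="gene_id")
        if results.scan is not None:
            _write_tsv(results.scan.table, outdir / "soft_threshold_scan.tsv", config,
                       index=False)
        _write_tsv(trait_table, outdir / "module_trait_correlation.tsv", config, index=False)
        if enrichment:
            frame = pd.DataFrame([e.__dict__ for e in enrichment])
            _write_tsv(frame, outdir / "enrichment.tsv", config, index=False)
        for tissue, tris in triad_categories.items():
            frame = pd.DataFrame(
                [(t.triad_id, t.cA, t.cB, t.cD, t.category) for t in tris],
                columns=["triad_id", "cA", "cB", "cD", "category"],
            )
            _write_tsv(frame, outdir / f"triad_categories_{tissue}.tsv", config, index=False)
        with open(outdir / "summary.txt", "w", encoding="utf-8") as handle:
            handle.write(_header(config))
            handle.write(report.summary_text() + "\n")
        with open(outdir / "config.yaml", "w", encoding="utf-8") as handle:
            yaml.safe_dump(config.to_dict(), handle, sort_keys=True)
    return report
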