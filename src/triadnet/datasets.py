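"""Synthetic allopolyploid expression datasets with planted ground truth.

The generator emulates the design of a polyploid (wheat-like) expression
atlas: samples from a configurable set of tissue types, co-expressed gene
modules driven by latent per-sample factors (optionally elevated in one
tissue, so the module correlates with it), homeolog triads whose members
split a shared total expression according to a contribution vector drawn
near one of the seven expression-bias centroids, per-sample library-size
variation, and Poisson (optionally over-dispersed) counts.  Every planted
feature is returned as ground truth so downstream stages can be scored.

Gene lengths are fixed at 1 kb, so TPM reduces to depth-normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homeolog import CATEGORY_CENTROIDS, CATEGORY_ORDER
from .io import (
    ExpressionMatrix,
    HomeologTable,
    SampleTable,
    write_expression_tsv,
    write_homeolog_table,
    write_sample_table,
)
from .network import ModulePartition

__all__ = [
    "ConfigError",
    "ModuleSpec",
    "SynthConfig",
    "PlantedSignal",
    "PlantedTriads",
    "SynthDataset",
    "plant_modules",
    "plant_triads",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_TISSUES = (
    "grain",
    "leaves",
    "roots",
    "meiotic_anther",
    "spike",
    "floral_organs",
    "stem",
    "shoots",
)

# Small uniform floor added to centroids before scaling by the concentration,
# so Dirichlet parameters stay positive for centroids with zero components.
# The floor leaves the balanced centroid exactly at (1/3, 1/3, 1/3).
_CENTROID_FLOOR = 0.01


class ConfigError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass
class ModuleSpec:
    module_id: int
    n_genes: int
    associated_tissue: str | None = None
    signal_sd: float = 2.0


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(1, 80, "meiotic_anther"),
        ModuleSpec(2, 80, "leaves"),
        ModuleSpec(3, 80, "roots"),
        ModuleSpec(4, 80, None),
    ]


def _default_mixture() -> dict[str, float]:
    mix = {"balanced": 0.70}
    for g in "ABD":
        mix[f"{g} suppressed"] = 0.06
        mix[f"{g} dominant"] = 0.04
    return mix


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults give the "easy" desk-scale design: 8 tissues x 5 samples
    (40 samples), 4 planted modules of 80 genes (one meiotic-anther-,
    one leaf-, one root-associated, one tissue-free) plus 180 background
    genes (500 genes total), a balanced-majority triad category mixture,
    and Poisson counts at library depths of 0.5-2 million.
    """

    tissue_labels: tuple[str, ...] = DEFAULT_TISSUES
    n_samples_per_tissue: int | Mapping[str, int] = 5
    module_specs: list[ModuleSpec] = field(default_factory=_default_modules)
    n_background_genes: int = 180
    triad_fraction: float = 0.6
    category_mixture: Mapping[str, float] = field(default_factory=_default_mixture)
    centroid_concentration: float = 200.0
    noise_sd: float = 1.0
    tissue_effect: float = 3.0  # factor shift in associated tissue, x signal_sd
    library_size_range: tuple[float, float] = (5e5, 2e6)
    dispersion: float = 0.0  # NB over-dispersion; 0 = Poisson
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.tissue_labels)) != len(self.tissue_labels):
            raise ConfigError("tissue labels must be unique")
        for tissue in self.tissue_labels:
            if self.samples_for(tissue) < 1:
                raise ConfigError(f"tissue {tissue!r} has zero samples")
        mix = dict(self.category_mixture)
        if set(mix) - set(CATEGORY_ORDER):
            raise ConfigError(f"unknown categories {sorted(set(mix) - set(CATEGORY_ORDER))}")
        probs = np.array([mix.get(c, 0.0) for c in CATEGORY_ORDER], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("category_mixture must be a probability vector summing to 1")
        if not 0.0 <= self.triad_fraction <= 1.0:
            raise ConfigError("triad_fraction must be in [0, 1]")
        if self.n_background_genes < 0 or any(s.n_genes < 0 for s in self.module_specs):
            raise ConfigError("gene counts must be nonnegative")
        ids = [s.module_id for s in self.module_specs]
        if len(set(ids)) != len(ids) or 0 in ids:
            raise ConfigError("module ids must be unique and nonzero")
        for spec in self.module_specs:
            if spec.associated_tissue is not None and spec.associated_tissue not in self.tissue_labels:
                raise ConfigError(f"unknown associated tissue {spec.associated_tissue!r}")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be positive with min <= max")
        if self.centroid_concentration <= 0:
            raise ConfigError("centroid_concentration must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")

    def samples_for(self, tissue: str) -> int:
        if isinstance(self.n_samples_per_tissue, Mapping):
            return int(self.n_samples_per_tissue.get(tissue, 0))
        return int(self.n_samples_per_tissue)

    def sample_table(self) -> SampleTable:
        rows = []
        for tissue in self.tissue_labels:
            for rep in range(1, self.samples_for(tissue) + 1):
                rows.append((f"{tissue}_{rep:02d}", tissue, "synthetic"))
        return SampleTable(pd.DataFrame(rows, columns=["sample_id", "tissue", "study"]))

    @property
    def n_genes(self) -> int:
        return sum(s.n_genes for s in self.module_specs) + self.n_background_genes


# ---------------------------------------------------------------------------
# gene / homeolog-group scaffolding


@dataclass
class _Group:
    group_id: str
    gene_ids: tuple[str, ...]  # length 3 (triad, order A/B/D) or 1 (monad)
    subgenomes: tuple[str, ...]
    module: int


def _build_groups(config: SynthConfig) -> list[_Group]:
    """Deterministic gene/group layout: triads first within each module."""
    groups: list[_Group] = []
    gene_counter = 0
    group_counter = 0
    blocks = [(s.module_id, s.n_genes) for s in config.module_specs]
    blocks.append((0, config.n_background_genes))
    for module, n_genes in blocks:
        n_triads = int(np.floor(n_genes * config.triad_fraction / 3.0))
        n_monads = n_genes - 3 * n_triads
        for _ in range(n_triads):
            group_counter += 1
            gid = f"HG{group_counter:05d}"
            genes = tuple(f"G{gene_counter + i + 1:05d}{s}" for i, s in enumerate("ABD"))
            gene_counter += 3
            groups.append(_Group(gid, genes, ("A", "B", "D"), module))
        for i in range(n_monads):
            group_counter += 1
            gid = f"HG{group_counter:05d}"
            sub = "ABD"[i % 3]
            gene = (f"G{gene_counter + 1:05d}{sub}",)
            gene_counter += 1
            groups.append(_Group(gid, gene, (sub,), module))
    return groups


@dataclass
class PlantedSignal:
    """Latent module structure before noise and counts."""

    signal: pd.DataFrame  # gene x sample latent log2 signal (no noise)
    partition: ModulePartition  # truth module labels, 0 = background
    factors: pd.DataFrame  # module x sample latent factors
    loadings: pd.Series  # per-gene loading on its module factor


def plant_modules(
    config: SynthConfig, rng: np.random.Generator, groups: list[_Group] | None = None
) -> PlantedSignal:
    """Draw module factors and per-gene loadings; build the latent signal.

    Each module's factor is N(0, signal_sd^2) per sample, shifted upward by
    ``tissue_effect x signal_sd`` in the associated tissue's samples.  Each
    gene's signal is loading x factor; background genes have zero signal.
    Members of one homeolog group share a loading (they split one
    transcriptional total).
    """
    if not config.module_specs:
        raise ConfigError("module_specs must be nonempty")
    config.validate()
    if groups is None:
        groups = _build_groups(config)
    samples = config.sample_table()
    sample_ids = samples.sample_ids
    tissue_of = dict(zip(samples.frame["sample_id"], samples.frame["tissue"]))
    factors = {}
    for spec in config.module_specs:
        if spec.signal_sd == 0.0:
            warnings.warn(
                f"module {spec.module_id}: signal_sd = 0 gives a constant factor; "
                "within-module correlations are undefined",
                stacklevel=2,
            )
        base = rng.normal(0.0, 1.0, size=len(sample_ids)) * spec.signal_sd
        if spec.associated_tissue is not None:
            shift = np.array(
                [tissue_of[s] == spec.associated_tissue for s in sample_ids], dtype=float
            )
            base = base + config.tissue_effect * spec.signal_sd * shift
        factors[spec.module_id] = base
    factor_frame = pd.DataFrame(factors, index=sample_ids).T
    factor_frame.index.name = "module"

    gene_ids: list[str] = []
    labels: dict[str, int] = {}
    loadings: dict[str, float] = {}
    signal_rows = []
    for group in groups:
        loading = float(rng.uniform(0.5, 1.5))
        for gene in group.gene_ids:
            if gene in labels:
                raise ConfigError(f"overlapping gene id {gene!r}")
            gene_ids.append(gene)
            labels[gene] = group.module
            loadings[gene] = loading if group.module != 0 else 0.0
            if group.module != 0:
                signal_rows.append(loading * factor_frame.loc[group.module].to_numpy())
            else:
                signal_rows.append(np.zeros(len(sample_ids)))
    signal = pd.DataFrame(signal_rows, index=gene_ids, columns=sample_ids)
    return PlantedSignal(
        signal=signal,
        partition=ModulePartition(labels),
        factors=factor_frame,
        loadings=pd.Series(loadings, name="loading"),
    )


@dataclass
class PlantedTriads:
    homeologs: HomeologTable
    categories: dict[str, str]  # triad_id -> bias category
    contributions: pd.DataFrame  # triad x (cA, cB, cD)


def _dirichlet_alpha(category: str, concentration: float) -> np.ndarray:
    centroid = np.asarray(CATEGORY_CENTROIDS[category], dtype=float)
    floored = (centroid + _CENTROID_FLOOR) / (1.0 + 3.0 * _CENTROID_FLOOR)
    return concentration * floored


def plant_triads(
    config: SynthConfig, rng: np.random.Generator, groups: list[_Group] | None = None
) -> PlantedTriads:
    """Assign bias categories and contribution vectors to planted triads.

    Categories are sampled from ``category_mixture``; contributions are
    Dirichlet draws centered on the (floored) category centroid with the
    configured concentration.  ``centroid_concentration = inf`` returns the
    centroid's floored mean direction exactly.
    """
    config.validate()
    if groups is None:
        groups = _build_groups(config)
    rows = []
    for group in groups:
        for gene, sub in zip(group.gene_ids, group.subgenomes):
            rows.append((group.group_id, gene, sub))
    table = HomeologTable(pd.DataFrame(rows, columns=["group_id", "gene_id", "subgenome"]))
    probs = np.array(
        [dict(config.category_mixture).get(c, 0.0) for c in CATEGORY_ORDER], dtype=float
    )
    categories: dict[str, str] = {}
    contributions = {}
    for group in groups:
        if len(group.gene_ids) != 3:
            continue
        category = CATEGORY_ORDER[int(rng.choice(len(CATEGORY_ORDER), p=probs))]
        alpha = _dirichlet_alpha(category, 1.0)
        if np.isinf(config.centroid_concentration):
            draw = alpha / alpha.sum()
        else:
            draw = rng.dirichlet(alpha * config.centroid_concentration)
        categories[group.group_id] = category
        contributions[group.group_id] = draw
    frame = pd.DataFrame(contributions, index=["cA", "cB", "cD"]).T
    frame.index.name = "triad_id"
    return PlantedTriads(table, categories, frame)


@dataclass
class SynthDataset:
    """A generated dataset plus its planted ground truth."""

    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    samples: SampleTable
    homeologs: HomeologTable
    truth_modules: ModulePartition
    truth_categories: dict[str, str]
    truth_contributions: pd.DataFrame
    truth_factors: pd.DataFrame
    truth_loadings: pd.Series
    config: SynthConfig


def generate_dataset(config: SynthConfig | None = None, seed: int | None = None) -> SynthDataset:
    """Generate a complete synthetic dataset (deterministic given the seed).

    Pipeline: latent log2 expression = baseline + module signal + noise at
    homeolog-group level; triad members split the group's linear total by
    the planted contribution vector; expected counts are
    library_size x relative expression; counts are Poisson (gamma-Poisson
    when ``dispersion > 0``); TPM is recomputed from counts at unit gene
    length, so every TPM column sums to one million.
    """
    config = config if config is not None else SynthConfig()
    if seed is not None:
        config = SynthConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = _build_groups(config)
    samples = config.sample_table()
    sample_ids = samples.sample_ids
    n_samples = len(sample_ids)

    planted = plant_modules(config, rng, groups)
    triads = plant_triads(config, rng, groups)

    # group-level latent log2 totals: baseline + signal + shared noise
    linear_rows = {}
    for group in groups:
        baseline = rng.uniform(4.0, 9.0)
        noise = rng.normal(0.0, config.noise_sd, size=n_samples)
        rep_gene = group.gene_ids[0]
        log_total = baseline + planted.signal.loc[rep_gene].to_numpy() + noise
        total = np.power(2.0, log_total)
        if len(group.gene_ids) == 3:
            contrib = triads.contributions.loc[group.group_id].to_numpy()
            for gene, c in zip(group.gene_ids, contrib):
                linear_rows[gene] = total * c
        else:
            linear_rows[group.gene_ids[0]] = total
    gene_ids = [g for group in groups for g in group.gene_ids]
    linear = pd.DataFrame(
        np.array([linear_rows[g] for g in gene_ids]), index=gene_ids, columns=sample_ids
    )

    lib_lo, lib_hi = config.library_size_range
    libraries = rng.uniform(lib_lo, lib_hi, size=n_samples)
    rel = linear.to_numpy() / linear.to_numpy().sum(axis=0, keepdims=True)
    mean_counts = rel * libraries[None, :]
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        mean_counts = rng.gamma(shape, mean_counts / shape)
    counts = rng.poisson(mean_counts).astype(np.int64)

    counts_frame = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    # unit (1 kb) gene lengths: TPM = counts rescaled to a column sum of 1e6
    colsum = counts_frame.sum(axis=0).replace(0, 1)
    tpm_frame = counts_frame / colsum * 1e6

    return SynthDataset(
        counts=ExpressionMatrix(counts_frame.astype(float), unit="count"),
        tpm=ExpressionMatrix(tpm_frame, unit="TPM"),
        samples=samples,
        homeologs=triads.homeologs,
        truth_modules=planted.partition,
        truth_categories=triads.categories,
        truth_contributions=triads.contributions,
        truth_factors=planted.factors,
        truth_loadings=planted.loadings,
        config=config,
    )


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> None:
    """Write counts/TPM/sample/homeolog tables and truth labels as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(dataset.counts, outdir / "counts.tsv")
    write_expression_tsv(dataset.tpm, outdir / "tpm.tsv")
    write_sample_table(dataset.samples, outdir / "samples.tsv")
    write_homeolog_table(dataset.homeologs, outdir / "homeologs.tsv")
    dataset.truth_modules.labels.rename("module").to_csv(
        outdir / "truth_modules.tsv", sep="\t", index_label="gene_id"
    )
    truth = dataset.truth_contributions.copy()
    truth["category"] = [dataset.truth_categories[t] for t in truth.index]
    truth.to_csv(outdir / "truth_triads.tsv", sep="\t", index_label="triad_id")
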