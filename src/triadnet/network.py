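"""Weighted co-expression network construction and module detection.

The model follows the WGCNA recipe: a robust gene–gene correlation
(biweight midcorrelation, bicor), raised to a soft-threshold power chosen by
the scale-free topology criterion, gives a signed-hybrid adjacency
a_ij = s_ij^beta for positive correlations (0 otherwise).  The adjacency is
transformed into an (unsigned) topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj,   k_i = sum_u a_iu,

whose dissimilarity 1 - TOM feeds average-linkage hierarchical clustering.
Clusters are cut statically, filtered by a minimum module size, and modules
with near-identical eigengenes are merged.  A module eigengene (ME) is the
first principal component of the module's standardized expression; kME is
the signed correlation of a gene with an ME and ranks hub genes.

:class:`CoexpressionNetwork` packages the recipe as a model object whose
``fit()`` returns a :class:`CoexpressionResults` carrying the partition,
eigengenes, kME table, soft-threshold scan and summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "SoftThresholdScan",
    "ModulePartition",
    "EigengeneMatrix",
    "bicor_matrix",
    "pearson_matrix",
    "scale_free_fit",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "merge_modules",
    "module_eigengenes",
    "signed_kme",
    "hub_genes",
    "CoexpressionNetwork",
    "CoexpressionResults",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame
    method: str  # bicor / pearson
    fallback_genes: list[str] = field(default_factory=list)
    zero_variance_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded adjacency; stored with unit diagonal.

    ``values`` (diagonal 1) is the TOM input view; ``values_diag_zero`` is
    the connectivity view.
    """

    values: pd.DataFrame
    beta: float
    network_type: str  # signed_hybrid / unsigned

    @property
    def values_diag_zero(self) -> pd.DataFrame:
        out = self.values.copy()
        np.fill_diagonal(out.to_numpy(), 0.0)
        return out

    @property
    def connectivity(self) -> pd.Series:
        k = self.values.sum(axis=1) - np.diag(self.values.to_numpy())
        k.name = "k"
        return k


@dataclass
class TOMMatrix:
    similarity: pd.DataFrame  # unit diagonal

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.similarity

    @property
    def gene_ids(self) -> list[str]:
        return list(self.similarity.index)


@dataclass
class SoftThresholdScan:
    """Per-power scale-free fit diagnostics and the chosen power.

    ``table`` columns: power, r_squared (signed fit index), slope, gamma_hat,
    mean_k, median_k, max_k.  ``chosen_beta`` is the smallest scanned power
    whose signed fit index exceeds ``target_fit`` (None if none qualifies).
    """

    table: pd.DataFrame
    chosen_beta: int | None
    target_fit: float


class ModulePartition:
    """Gene -> module label map; label 0 marks unassigned genes."""

    def __init__(self, labels: Mapping[str, int] | pd.Series):
        self.labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels).astype(int)
        if (self.labels < 0).any():
            raise ValueError("module labels must be nonnegative")

    def __getitem__(self, gene: str) -> int:
        return int(self.labels[gene])

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels.index)

    def items(self):
        return self.labels.items()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def modules(self) -> list[int]:
        """Nonzero module labels, ascending."""
        return sorted(set(self.labels) - {0})

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels != 0].value_counts().sort_index()
        sizes.name = "size"
        return sizes

    @property
    def n_assigned(self) -> int:
        return int((self.labels != 0).sum())


@dataclass
class EigengeneMatrix:
    """Module eigengenes: one unit-norm per-sample profile per module."""

    values: pd.DataFrame  # module x sample
    variance_explained: pd.Series
    flagged_modules: list[int] = field(default_factory=list)

    @property
    def modules(self) -> list[int]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# correlation

_BICOR_TUNING = 9.0


def _bicor_rows(values: np.ndarray, max_p_outliers: float) -> tuple[np.ndarray, list[int], list[int]]:
    """Per-gene weighted, centered, unit-norm rows for bicor.

    Returns (rows, pearson_fallback_indices, zero_variance_indices).  Genes
    whose MAD is zero fall back to ordinary (mean-centered, unweighted)
    rows; mixed pairs then yield the hybrid bicor/Pearson correlation.
    """
    n_genes, n_samples = values.shape
    rows = np.zeros_like(values, dtype=float)
    fallback: list[int] = []
    zerovar: list[int] = []
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1)
    for i in range(n_genes):
        x = values[i]
        if mad[i] == 0.0:
            centered = x - x.mean()
            norm = np.sqrt((centered**2).sum())
            if norm == 0.0:
                zerovar.append(i)
                continue
            fallback.append(i)
            rows[i] = centered / norm
            continue
        u = (x - med[i, 0]) / (_BICOR_TUNING * mad[i])
        if 0.0 < max_p_outliers < 1.0:
            # Cap so that at most max_p_outliers of samples per tail get zero
            # weight: rescale each side so its outer quantile maps to +-1.
            q_low, q_high = np.quantile(u, [max_p_outliers, 1.0 - max_p_outliers])
            if q_low < -1.0:
                u = np.where(u < 0, u / abs(q_low), u)
            if q_high > 1.0:
                u = np.where(u > 0, u / q_high, u)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        a = w * (x - med[i, 0])
        norm = np.sqrt((a**2).sum())
        if norm == 0.0:
            zerovar.append(i)
            continue
        rows[i] = a / norm
    return rows, fallback, zerovar


def bicor_matrix(expr: ExpressionMatrix, max_p_outliers: float = 0.05) -> CorrelationMatrix:
    """Biweight midcorrelation between all gene pairs.

    Observations are weighted by (1 - u^2)^2 with u the deviation from the
    gene's median in units of 9 MADs; at most ``max_p_outliers`` of samples
    per tail can receive zero weight.  Genes with zero MAD fall back to
    ordinary correlation (reported in ``fallback_genes``); genes with zero
    variance get zero correlation and are reported in
    ``zero_variance_genes``.
    """
    if expr.n_samples < 4:
        raise ValueError("bicor needs at least 4 samples")
    values = expr.values.to_numpy(dtype=float)
    rows, fallback, zerovar = _bicor_rows(values, max_p_outliers)
    cor = rows @ rows.T
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    for i in zerovar:
        cor[i, :] = 0.0
        cor[:, i] = 0.0
        cor[i, i] = 1.0
    genes = expr.gene_ids
    frame = pd.DataFrame(cor, index=genes, columns=genes)
    return CorrelationMatrix(
        frame,
        method="bicor",
        fallback_genes=[genes[i] for i in fallback],
        zero_variance_genes=[genes[i] for i in zerovar],
    )


def pearson_matrix(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Ordinary Pearson correlation between all gene pairs."""
    values = expr.values.to_numpy(dtype=float)
    sd = values.std(axis=1)
    zerovar = [i for i in range(len(sd)) if sd[i] == 0.0]
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    genes = expr.gene_ids
    return CorrelationMatrix(
        pd.DataFrame(cor, index=genes, columns=genes),
        method="pearson",
        zero_variance_genes=[genes[i] for i in zerovar],
    )


# ---------------------------------------------------------------------------
# soft threshold


def scale_free_fit(k: Sequence[float], n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity distribution.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean k per nonempty bin).
    Returns (signed_r_squared, gamma_hat) where the sign is minus the slope's
    sign (scale-free networks have negative slope) and gamma_hat = -slope.
    """
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("connectivities must be nonnegative")
    if np.ptp(k) == 0.0:
        raise ValueError("all connectivities equal: scale-free fit undefined")
    counts, edges = np.histogram(k, bins=n_bins)
    mean_k = np.full(n_bins, np.nan)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        if counts[b] > 0:
            mean_k[b] = k[which == b].mean()
    freq = counts / counts.sum()
    usable = (counts > 0) & (mean_k > 0)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable bins: scale-free fit undefined")
    fit = linregress(np.log10(mean_k[usable]), np.log10(freq[usable]))
    signed_r2 = -np.sign(fit.slope) * fit.rvalue**2
    return float(signed_r2), float(-fit.slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: Iterable[int] = range(1, 21),
    target_fit: float = 0.9,
    network_type: str = "signed_hybrid",
    corr_method: str = "bicor",
    max_p_outliers: float = 0.05,
    n_bins: int = 10,
    correlation: CorrelationMatrix | None = None,
) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers for scale-free topology.

    For each power the adjacency and its connectivity distribution are
    evaluated; the chosen beta is the smallest power whose signed fit index
    exceeds ``target_fit``.  If none qualifies, ``chosen_beta`` is None and a
    warning is emitted.
    """
    powers = list(powers)
    if not powers or any(p <= 0 for p in powers) or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending positive sequence")
    if correlation is None:
        correlation = (
            bicor_matrix(expr, max_p_outliers)
            if corr_method == "bicor"
            else pearson_matrix(expr)
        )
    rows = []
    for power in powers:
        adj = adjacency(correlation, beta=power, network_type=network_type)
        k = adj.connectivity.to_numpy()
        try:
            r2, gamma = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, gamma = np.nan, np.nan
        rows.append(
            (power, r2, -gamma, gamma, float(k.mean()), float(np.median(k)), float(k.max()))
        )
    table = pd.DataFrame(
        rows,
        columns=["power", "r_squared", "slope", "gamma_hat", "mean_k", "median_k", "max_k"],
    )
    qualifying = table.loc[table["r_squared"] > target_fit, "power"]
    chosen = int(qualifying.iloc[0]) if len(qualifying) else None
    if chosen is None:
        warnings.warn(
            f"no scanned power reaches scale-free fit index {target_fit}", stacklevel=2
        )
    return SoftThresholdScan(table=table, chosen_beta=chosen, target_fit=target_fit)


# ---------------------------------------------------------------------------
# adjacency and topological overlap


def adjacency(
    cor: CorrelationMatrix, beta: float, network_type: str = "signed_hybrid"
) -> AdjacencyMatrix:
    """Soft-threshold a correlation matrix.

    signed_hybrid: a = s^beta for s > 0, else 0; unsigned: a = |s|^beta.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    s = cor.values.to_numpy(dtype=float)
    if network_type == "signed_hybrid":
        a = np.where(s > 0, np.power(np.clip(s, 0.0, None), beta), 0.0)
    elif network_type == "unsigned":
        a = np.power(np.abs(s), beta)
    else:
        raise ValueError(f"unknown network type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    frame = pd.DataFrame(a, index=cor.values.index, columns=cor.values.columns)
    return AdjacencyMatrix(frame, beta=float(beta), network_type=network_type)


def tom_similarity(adj: AdjacencyMatrix | pd.DataFrame) -> TOMMatrix:
    """Unsigned topological overlap of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    frame = adj.values_diag_zero if isinstance(adj, AdjacencyMatrix) else adj.copy()
    a = frame.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of a is 0, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return TOMMatrix(pd.DataFrame(tom, index=frame.index, columns=frame.columns))


# ---------------------------------------------------------------------------
# module detection


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Renumber nonzero modules 1.. by decreasing size (ties: smallest member id)."""
    out = pd.Series(0, index=labels.index, dtype=int)
    groups = []
    for old in sorted(set(labels) - {0}):
        members = labels.index[labels == old]
        groups.append((-len(members), min(members), old))
    for new, (_, _, old) in enumerate(sorted(groups), start=1):
        out[labels == old] = new
    return out


def detect_modules(
    diss: TOMMatrix | pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of the TOM dissimilarity with a static cut.

    The dendrogram is cut at ``cut_height`` x (maximum merge height);
    clusters smaller than ``min_module_size`` go to module 0; surviving
    clusters are labelled 1.. by decreasing size.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    frame = diss.dissimilarity if isinstance(diss, TOMMatrix) else diss
    d = frame.to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("dissimilarities must be finite")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    genes = list(frame.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    link = linkage(squareform(d, checks=False), method="average")
    max_height = link[:, 2].max()
    if max_height == 0.0:
        raw = pd.Series(1, index=genes)
    else:
        clusters = fcluster(link, t=cut_height * max_height, criterion="distance")
        raw = pd.Series(clusters, index=genes)
    sizes = raw.value_counts()
    small = sizes.index[sizes < min_module_size]
    raw[raw.isin(small)] = 0
    return ModulePartition(_relabel_by_size(raw))


def module_eigengenes(expr: ExpressionMatrix, partition: ModulePartition) -> EigengeneMatrix:
    """First principal component of each module's standardized expression.

    Member gene profiles are z-scored across samples; the eigengene is the
    leading right singular vector over samples, sign-oriented so its mean
    correlation with member genes is nonnegative, with unit Euclidean norm.
    Modules whose members all have zero variance are flagged (NaN profile).
    """
    samples = expr.sample_ids
    values = expr.values
    profiles = {}
    varexp = {}
    flagged = []
    for m in partition.modules:
        members = partition.genes_in(m)
        sub = values.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        keep = sd > 0
        if keep.sum() == 0:
            flagged.append(m)
            profiles[m] = np.full(len(samples), np.nan)
            varexp[m] = np.nan
            continue
        z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        member_cor = z @ me  # proportional to correlation, common positive scale
        if member_cor.mean() < 0:
            me = -me
        profiles[m] = me
        varexp[m] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(profiles, index=samples).T
    frame.index.name = "module"
    return EigengeneMatrix(frame, pd.Series(varexp, name="variance_explained"), flagged)


def merge_modules(
    partition: ModulePartition,
    expr: ExpressionMatrix,
    merge_cut_height: float = 0.15,
) -> ModulePartition:
    """Merge modules whose eigengenes are closer than ``merge_cut_height``.

    Iteratively merges the module pair with the most correlated eigengenes
    while 1 - cor(ME_a, ME_b) < merge_cut_height, recomputing eigengenes
    after every merge.  Labels are re-assigned by decreasing size at the end.
    """
    if not 0.0 < merge_cut_height < 1.0:
        raise ValueError("merge_cut_height must be in (0, 1)")
    labels = partition.labels.copy()
    while True:
        current = ModulePartition(labels)
        modules = current.modules
        if len(modules) < 2:
            break
        eig = module_eigengenes(expr, current)
        me = eig.values.dropna()
        if len(me) < 2:
            break
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        a, b = int(me.index[i]), int(me.index[j])
        labels[labels == max(a, b)] = min(a, b)
    return ModulePartition(_relabel_by_size(labels))


def signed_kme(expr: ExpressionMatrix, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Signed correlation of every gene with every module eigengene.

    Returns a gene x module frame; zero-variance genes get NaN.
    """
    x = expr.values.to_numpy(dtype=float)
    me = eigengenes.values.to_numpy(dtype=float)
    xs = x.std(axis=1)
    ms = me.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    mc = me - me.mean(axis=1, keepdims=True)
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        kme = (xc @ mc.T / n) / np.outer(xs, ms)
    kme[xs == 0, :] = np.nan
    out = pd.DataFrame(kme, index=expr.gene_ids, columns=eigengenes.values.index)
    return out.clip(-1.0, 1.0)


def hub_genes(
    kme: pd.DataFrame, partition: ModulePartition, n: int = 10
) -> dict[int, list[str]]:
    """Top-n members of each module by decreasing kME (ties: gene id order)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: dict[int, list[str]] = {}
    for m in partition.modules:
        members = [g for g in partition.genes_in(m) if g in kme.index]
        ranked = sorted(members, key=lambda g: (-kme.at[g, m], g))
        out[m] = ranked[:n]
    return out


# ---------------------------------------------------------------------------
# model / results


class CoexpressionNetwork:
    """Weighted co-expression network model over a normalized expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples, unit ``normalized`` (log scale) recommended.
    network_type : str
        ``signed_hybrid`` (default) or ``unsigned``.
    corr_method : str
        ``bicor`` (default) or ``pearson``.
    max_p_outliers : float
        Per-tail cap on the fraction of zero-weight samples in bicor.

    Examples
    --------
    >>> model = CoexpressionNetwork(expr)
    >>> res = model.fit(min_module_size=30, merge_cut_height=0.15)
    >>> print(res.summary())
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        network_type: str = "signed_hybrid",
        corr_method: str = "bicor",
        max_p_outliers: float = 0.05,
    ):
        if network_type not in ("signed_hybrid", "unsigned"):
            raise ValueError(f"unknown network type {network_type!r}")
        self.expr = expr
        self.network_type = network_type
        self.corr_method = corr_method
        self.max_p_outliers = max_p_outliers
        self._correlation: CorrelationMatrix | None = None

    @property
    def correlation(self) -> CorrelationMatrix:
        if self._correlation is None:
            self._correlation = (
                bicor_matrix(self.expr, self.max_p_outliers)
                if self.corr_method == "bicor"
                else pearson_matrix(self.expr)
            )
        return self._correlation

    def pick_soft_threshold(
        self,
        powers: Iterable[int] = range(1, 21),
        target_fit: float = 0.9,
        n_bins: int = 10,
    ) -> SoftThresholdScan:
        return pick_soft_threshold(
            self.expr,
            powers=powers,
            target_fit=target_fit,
            network_type=self.network_type,
            correlation=self.correlation,
            n_bins=n_bins,
        )

    def fit(
        self,
        beta: int | None = None,
        powers: Iterable[int] = range(1, 21),
        target_fit: float = 0.9,
        min_module_size: int = 30,
        merge_cut_height: float = 0.15,
        cut_height: float = 0.99,
    ) -> "CoexpressionResults":
        """Build the network and detect, filter and merge modules."""
        scan = None
        if beta is None:
            scan = self.pick_soft_threshold(powers=powers, target_fit=target_fit)
            if scan.chosen_beta is not None:
                beta = scan.chosen_beta
            else:
                # fall back to the best-fitting scanned power
                beta = int(scan.table.loc[scan.table["r_squared"].idxmax(), "power"])
                warnings.warn(
                    f"no power reached fit {target_fit}; using best-fit power {beta}",
                    stacklevel=2,
                )
        adj = adjacency(self.correlation, beta=beta, network_type=self.network_type)
        tom = tom_similarity(adj)
        partition = detect_modules(tom, min_module_size=min_module_size, cut_height=cut_height)
        partition = merge_modules(partition, self.expr, merge_cut_height=merge_cut_height)
        eigengenes = module_eigengenes(self.expr, partition)
        kme = signed_kme(self.expr, eigengenes)
        params = {
            "beta": int(beta),
            "network_type": self.network_type,
            "corr_method": self.corr_method,
            "max_p_outliers": self.max_p_outliers,
            "min_module_size": int(min_module_size),
            "merge_cut_height": float(merge_cut_height),
            "cut_height": float(cut_height),
            "target_fit": float(target_fit),
        }
        return CoexpressionResults(
            model=self,
            scan=scan,
            adjacency=adj,
            tom=tom,
            partition=partition,
            eigengenes=eigengenes,
            kme=kme,
            params=params,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: partition, eigengenes, kME, diagnostics."""

    model: CoexpressionNetwork
    scan: SoftThresholdScan | None
    adjacency: AdjacencyMatrix
    tom: TOMMatrix
    partition: ModulePartition
    eigengenes: EigengeneMatrix = None  # type: ignore[assignment]
    kme: pd.DataFrame = None  # type: ignore[assignment]
    params: dict = None  # type: ignore[assignment]

    @property
    def expr(self) -> ExpressionMatrix:
        return self.model.expr

    def module_sizes(self) -> pd.Series:
        return self.partition.module_sizes()

    @property
    def percent_assigned(self) -> float:
        return 100.0 * self.partition.n_assigned / len(self.partition)

    def hub_genes(self, n: int = 10) -> dict[int, list[str]]:
        return hub_genes(self.kme, self.partition, n=n)

    def trait_correlation(self, samples) -> pd.DataFrame:
        from . import traits

        indicators = traits.tissue_indicators(samples)
        return traits.module_trait_correlation(self.eigengenes, indicators)

    def extract_subnetwork(self, guides: Sequence[str], weight_min: float = 0.05):
        from . import subnet

        return subnet.extract_guide_subnetwork(self.tom, self.partition, guides, weight_min)

    def summary(self) -> str:
        sizes = self.module_sizes()
        lines = [
            "Co-expression network results",
            "=" * 46,
            f"genes                 {len(self.partition):>10d}",
            f"samples               {self.expr.n_samples:>10d}",
            f"soft threshold beta   {self.params['beta']:>10d}",
            f"network type          {self.params['network_type']:>14s}",
            f"modules               {len(sizes):>10d}",
            f"genes assigned        {self.partition.n_assigned:>10d} ({self.percent_assigned:.1f}%)",
        ]
        if len(sizes):
            lines += [
                f"module size mean      {sizes.mean():>10.1f}",
                f"module size median    {sizes.median():>10.1f}",
                f"module size range     {sizes.min():>5d} .. {sizes.max():<5d}",
            ]
        return "\n".join(lines)
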