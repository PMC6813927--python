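"""Gene-set and GO-term enrichment of network modules.

Each module is tested for over/under-representation of a gene set against a
background universe with a two-sided Fisher exact test; expected counts are
|set ∩ background| × |module ∩ background| / |background|.  GO terms are
tested per module with hypergeometric over-representation p-values and
Benjamini–Hochberg adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "set_enrichment", "go_enrichment", "bh_adjust"]


@dataclass
class EnrichmentResult:
    set_name: str
    module: int
    observed: int
    expected: float
    p: float
    fdr: float
    direction: str  # over / under / ns


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _module_members(partition: Mapping[str, int]) -> dict[int, set[str]]:
    members: dict[int, set[str]] = {}
    for gene, label in partition.items():
        members.setdefault(int(label), set()).add(gene)
    return members


def set_enrichment(
    partition: Mapping[str, int],
    gene_set: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
    set_name: str = "set",
    include_module_zero: bool = False,
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of one gene set in every module.

    The contingency table per module m is
    [[in-set & in-m, in-set & not-m], [not-set & in-m, not-set & not-m]]
    over the background universe.  ``direction`` is over/under when the
    two-sided p is below ``alpha`` and the observed count deviates from the
    expected count, else ``ns``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    genes_in_set = set(gene_set) & bg
    if not genes_in_set:
        raise ValueError("gene set does not intersect the background")
    members = _module_members(partition)
    modules = sorted(m for m in members if include_module_zero or m != 0)
    results: list[EnrichmentResult] = []
    pvals = []
    for m in modules:
        mod = members[m] & bg
        a = len(genes_in_set & mod)
        b = len(genes_in_set) - a
        c = len(mod) - a
        d = len(bg) - a - b - c
        expected = len(genes_in_set) * len(mod) / len(bg)
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        pvals.append(p)
        if p < alpha and a > expected:
            direction = "over"
        elif p < alpha and a < expected:
            direction = "under"
        else:
            direction = "ns"
        results.append(EnrichmentResult(set_name, m, a, expected, p, np.nan, direction))
    fdrs = bh_adjust(pvals)
    for res, fdr in zip(results, fdrs):
        res.fdr = float(fdr)
    return results


def go_enrichment(
    module_genes: Iterable[str],
    go_annotation: pd.DataFrame,
    background: Iterable[str],
    fdr_max: float = 0.05,
    method: str = "hypergeometric",
    gene_lengths: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-GO-term over-representation of a module's genes.

    ``go_annotation`` has columns gene_id / go_id.  Terms with no annotated
    background gene are skipped.  Returns a frame with columns go_id,
    observed, expected, p, fdr, enriched, sorted by p.

    ``method='hypergeometric'`` (default) treats every gene as equally
    likely to enter the module a priori.  ``method='length_weighted'``
    corrects for gene-length sampling bias with a Wallenius noncentral
    hypergeometric tail whose odds are the mean length of the term's genes
    over the mean length of the remaining background; it requires
    ``gene_lengths`` and reduces to the hypergeometric when lengths are
    constant.
    """
    if method not in ("hypergeometric", "length_weighted"):
        raise NotImplementedError(f"unsupported enrichment method {method!r}")
    if method == "length_weighted" and gene_lengths is None:
        raise ValueError("length_weighted enrichment requires gene_lengths")
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    module = set(module_genes) & bg
    ann = go_annotation[go_annotation["gene_id"].isin(bg)]
    rows = []
    n_bg, n_mod = len(bg), len(module)
    for go_id, grp in ann.groupby("go_id", sort=True):
        term_genes = set(grp["gene_id"])
        k_term = len(term_genes)
        observed = len(term_genes & module)
        expected = k_term * n_mod / n_bg
        if method == "length_weighted":
            assert gene_lengths is not None
            in_len = np.mean([gene_lengths.get(g, 1.0) for g in term_genes])
            rest = bg - term_genes
            out_len = np.mean([gene_lengths.get(g, 1.0) for g in rest]) if rest else 1.0
            odds = float(in_len / out_len)
            dist = stats.nchypergeom_wallenius(n_bg, k_term, n_mod, odds)
            p = float(dist.sf(observed - 1))
        else:
            # P(X >= observed) for X ~ Hypergeom(N=n_bg, K=k_term, n=n_mod)
            p = float(stats.hypergeom.sf(observed - 1, n_bg, k_term, n_mod))
        rows.append((go_id, observed, expected, p))
    frame = pd.DataFrame(rows, columns=["go_id", "observed", "expected", "p"])
    if len(frame):
        frame["fdr"] = bh_adjust(frame["p"].to_numpy())
        frame["enriched"] = frame["fdr"] < fdr_max
        frame = frame.sort_values(["p", "go_id"]).reset_index(drop=True)
    else:
        frame["fdr"] = []
        frame["enriched"] = []
    return frame


def resolve_overlaps(
    sets: Mapping[str, Sequence[str]], priority: Sequence[str]
) -> dict[str, list[str]]:
    """Assign genes appearing in several sets to the highest-priority one."""
    seen: set[str] = set()
    resolved: dict[str, list[str]] = {}
    for name in priority:
        members = [g for g in sets[name] if g not in seen]
        seen.update(members)
        resolved[name] = members
    return resolved
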