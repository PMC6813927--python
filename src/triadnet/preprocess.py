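"""Expression filtering and count normalization ahead of network construction.

A gene is considered expressed when its TPM exceeds a threshold (default
0.5) in at least one target sample — strictly, TPM > threshold.  Counts are
depth-normalized with median-of-ratios size factors and stabilised with
log2(x/sf + 1), a rank-preserving substitute for a variance-stabilizing
transform (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["FilterResult", "filter_expressed", "size_factors", "normalize"]


@dataclass
class FilterResult:
    kept_gene_ids: list[str]
    threshold: float
    qualifying_samples: list[str]

    @property
    def n_kept(self) -> int:
        return len(self.kept_gene_ids)


def filter_expressed(
    tpm: ExpressionMatrix,
    target_samples: Sequence[str],
    threshold: float = 0.5,
) -> FilterResult:
    """Keep genes with TPM strictly above ``threshold`` in >= 1 target sample."""
    target = list(target_samples)
    if not target:
        raise ValueError("target_samples must be nonempty")
    missing = set(target) - set(tpm.sample_ids)
    if missing:
        raise ValueError(f"target samples not in matrix: {sorted(missing)}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sub = tpm.values[target]
    keep = (sub > threshold).any(axis=1)
    return FilterResult(
        kept_gene_ids=list(sub.index[keep]),
        threshold=float(threshold),
        qualifying_samples=target,
    )


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per gene, the geometric mean across samples is formed over genes with no
    zero count; each sample's factor is the median over those genes of
    count / geometric mean.  No rescaling of the factors is applied.
    """
    values = counts.values.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    allpos = (values > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with nonzero counts in every sample")
    ref = values[allpos]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize(counts: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Depth-normalize and log-transform: value = log2(count / factor + 1)."""
    if set(factors.index) != set(counts.sample_ids):
        raise ValueError("size factors not aligned to samples")
    factors = factors.reindex(counts.sample_ids)
    if (factors <= 0).any():
        bad = factors.index[(factors <= 0).to_numpy()][0]
        raise ValueError(f"nonpositive size factor for sample {bad!r}")
    values = counts.values / factors.to_numpy()[None, :]
    return ExpressionMatrix(np.log2(values + 1.0), unit="normalized")
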