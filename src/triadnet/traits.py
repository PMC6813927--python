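"""Module–tissue correlation and selection of tissue-specific modules.

Each module eigengene is correlated (Pearson) with a 0/1 indicator per
tissue; significance uses the Student asymptotic t-test for a correlation,
t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom, two-sided, with
Benjamini–Hochberg adjustment over the full module x tissue family.  A
module is tissue-specific (e.g. meiosis-related) when r > r_high and
FDR < fdr_max for the target tissue while r < r_low or r <= 0 for every
other tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust
from .io import SampleTable
from .network import EigengeneMatrix

__all__ = [
    "tissue_indicators",
    "correlation_pvalue",
    "module_trait_correlation",
    "select_meiosis_modules",
    "top_tissue_modules",
]


def tissue_indicators(samples: SampleTable, tissue_order: list[str] | None = None) -> pd.DataFrame:
    """One-hot sample x tissue matrix (column order = configured tissue order)."""
    order = tissue_order if tissue_order is not None else samples.tissues
    unknown = set(samples.frame["tissue"]) - set(order)
    if unknown:
        raise ValueError(f"unknown tissues {sorted(unknown)}")
    frame = pd.DataFrame(
        0, index=samples.sample_ids, columns=list(order), dtype=int
    )
    for sid, tissue in zip(samples.frame["sample_id"], samples.frame["tissue"]):
        frame.at[sid, tissue] = 1
    return frame


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student asymptotic p for a correlation r at sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eigengenes: EigengeneMatrix, indicators: pd.DataFrame
) -> pd.DataFrame:
    """Correlate every eigengene with every tissue indicator.

    Returns a long-format frame with columns module, tissue, r, p, fdr; the
    BH family is the whole module x tissue grid.  Constant indicators yield
    NaN (flagged by the caller's downstream rules).
    """
    me = eigengenes.values
    n = me.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if list(indicators.index) != list(me.columns):
        indicators = indicators.reindex(me.columns)
        if indicators.isna().any().any():
            raise ValueError("indicator samples do not match eigengene samples")
    rows = []
    for module in me.index:
        x = me.loc[module].to_numpy(dtype=float)
        for tissue in indicators.columns:
            y = indicators[tissue].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0 or np.isnan(x).any():
                rows.append((module, tissue, np.nan, np.nan))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append((module, tissue, r, correlation_pvalue(r, n)))
    frame = pd.DataFrame(rows, columns=["module", "tissue", "r", "p"])
    fdr = np.full(len(frame), np.nan)
    ok = frame["p"].notna().to_numpy()
    if ok.any():
        fdr[ok] = bh_adjust(frame.loc[ok, "p"].to_numpy())
    frame["fdr"] = fdr
    return frame


def select_meiosis_modules(
    table: pd.DataFrame,
    target_tissue: str,
    r_high: float = 0.5,
    r_low: float = 0.3,
    fdr_max: float = 0.05,
) -> list[int]:
    """Modules strongly correlated with the target tissue and with no other.

    Selection rule: r > r_high and FDR < fdr_max with the target tissue, and
    for every other tissue r < r_low or r <= 0 (NaN correlations count as
    weak).  Returned in descending order of target-tissue r.
    """
    if target_tissue not in set(table["tissue"]):
        raise ValueError(f"target tissue {target_tissue!r} absent from table")
    selected = []
    for module, grp in table.groupby("module", sort=True):
        grp = grp.set_index("tissue")
        row = grp.loc[target_tissue]
        if not (row["r"] > r_high and row["fdr"] < fdr_max):
            continue
        others = grp.drop(index=target_tissue)
        weak = ((others["r"] < r_low) | (others["r"] <= 0) | others["r"].isna()).all()
        if weak:
            selected.append((float(row["r"]), module))
    return [m for _, m in sorted(selected, key=lambda t: (-t[0], t[1]))]


def top_tissue_modules(table: pd.DataFrame, tissue: str, n: int = 3) -> list[int]:
    """The n modules most correlated with a tissue (ties by module label)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sub = table[table["tissue"] == tissue].copy()
    if not len(sub):
        raise ValueError(f"tissue {tissue!r} absent from table")
    sub = sub.sort_values(["r", "module"], ascending=[False, True])
    return list(sub["module"].head(n))
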