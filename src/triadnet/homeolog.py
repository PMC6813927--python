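"""Homeolog copy-number and expression-bias analysis for allopolyploids.

A homeolog group in hexaploid wheat carries 0+ gene copies on each of the
A, B and D subgenomes.  Groups are binned into copy-number categories
(triad = 1:1:1, duplet, monad, other).  For triads, the relative expression
contribution of each homeolog,

    cA = TPM(A) / [TPM(A) + TPM(B) + TPM(D)]   (likewise cB, cD),

places the triad on the 2-simplex; the triad's bias category is the one of
seven ideal centroids (balanced, A/B/D dominant, A/B/D suppressed) at the
shortest Euclidean distance.  Centroids use exact fractions (1/3, 1/2), not
their 2-decimal roundings, so the decision regions keep the simplex's
three-fold symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CompartmentTable, ExpressionMatrix, SampleTable

__all__ = [
    "CATEGORY_CENTROIDS",
    "CATEGORY_ORDER",
    "CopyNumberCategory",
    "TriadContribution",
    "classify_homeolog_group",
    "mean_tissue_tpm",
    "relative_contributions",
    "classify_triad",
    "homeolog_labels",
    "balanced_percentage",
    "progenitor_comparison",
    "assign_compartment",
    "classify_triads_in_tissue",
]

# Tie-break priority: balanced, then suppressed A/B/D, then dominant A/B/D.
CATEGORY_ORDER: tuple[str, ...] = (
    "balanced",
    "A suppressed",
    "B suppressed",
    "D suppressed",
    "A dominant",
    "B dominant",
    "D dominant",
)

CATEGORY_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "A suppressed": (0.0, 0.5, 0.5),
    "B suppressed": (0.5, 0.0, 0.5),
    "D suppressed": (0.5, 0.5, 0.0),
    "A dominant": (1.0, 0.0, 0.0),
    "B dominant": (0.0, 1.0, 0.0),
    "D dominant": (0.0, 0.0, 1.0),
}

_CENTROID_ARRAY = np.array([CATEGORY_CENTROIDS[c] for c in CATEGORY_ORDER])


@dataclass
class CopyNumberCategory:
    group_id: str
    nA: int
    nB: int
    nD: int
    category: str  # triad / duplet / monad / other


@dataclass
class TriadContribution:
    triad_id: str
    cA: float
    cB: float
    cD: float
    category: str
    distances: dict[str, float] = field(default_factory=dict)


def classify_homeolog_group(nA: int, nB: int, nD: int, group_id: str = "") -> CopyNumberCategory:
    """Bin a homeolog group by its per-subgenome copy numbers."""
    counts = (nA, nB, nD)
    if any(c < 0 for c in counts):
        raise ValueError("copy numbers must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero copy numbers")
    if counts == (1, 1, 1):
        category = "triad"
    elif total == 2 and max(counts) == 1:
        category = "duplet"
    elif total == 1:
        category = "monad"
    else:
        category = "other"
    return CopyNumberCategory(group_id, nA, nB, nD, category)


def mean_tissue_tpm(
    tpm: ExpressionMatrix,
    samples: SampleTable,
    tissue: str,
    aggregate: str = "mean",
) -> pd.Series:
    """Per-gene mean (or median) TPM over one tissue's samples."""
    ids = samples.samples_of(tissue)
    if not ids:
        raise ValueError(f"no samples for tissue {tissue!r}")
    sub = tpm.values[ids]
    if aggregate == "mean":
        return sub.mean(axis=1)
    if aggregate == "median":
        return sub.median(axis=1)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def relative_contributions(tA: float, tB: float, tD: float) -> tuple[float, float, float]:
    """Normalize the three homeolog abundances to the 2-simplex."""
    if tA < 0 or tB < 0 or tD < 0:
        raise ValueError("abundances must be nonnegative")
    total = tA + tB + tD
    if total <= 0:
        raise ValueError("zero total expression: contributions undefined")
    return (tA / total, tB / total, tD / total)


def classify_triad(contribs: Sequence[float]) -> tuple[str, dict[str, float]]:
    """Nearest-centroid bias category for a contribution vector.

    Ties are broken by the fixed priority order balanced, suppressed A/B/D,
    dominant A/B/D.  Returns (category, distances-to-all-seven).
    """
    c = np.asarray(contribs, dtype=float)
    if c.shape != (3,) or abs(c.sum() - 1.0) > 1e-6 or (c < -1e-12).any():
        raise ValueError("contributions must be a length-3 simplex vector")
    dists = np.sqrt(((c[None, :] - _CENTROID_ARRAY) ** 2).sum(axis=1))
    best = int(np.argmin(dists))  # argmin keeps the first = highest priority
    return CATEGORY_ORDER[best], dict(zip(CATEGORY_ORDER, dists.tolist()))


def homeolog_labels(category: str) -> dict[str, str]:
    """Per-subgenome label (balanced/dominant/suppressed) for a triad category.

    A balanced triad labels all three homeologs balanced; "X dominant" labels
    X dominant and the other two suppressed; "X suppressed" labels X
    suppressed and the other two dominant.
    """
    if category == "balanced":
        return {"A": "balanced", "B": "balanced", "D": "balanced"}
    if category not in CATEGORY_ORDER:
        raise ValueError(f"unknown triad category {category!r}")
    genome, kind = category.split()
    other = "suppressed" if kind == "dominant" else "dominant"
    return {g: (kind if g == genome else other) for g in ("A", "B", "D")}


def balanced_percentage(
    gene_ids: Sequence[str], labels: Mapping[str, str]
) -> dict[str, float]:
    """Percentage of queried (labelled) genes in each expression-pattern class."""
    labelled = [labels[g] for g in gene_ids if g in labels]
    if not labelled:
        raise ValueError("no queried gene carries a homeolog expression label")
    out = {}
    for kind in ("balanced", "dominant", "suppressed"):
        out[kind] = 100.0 * sum(1 for l in labelled if l == kind) / len(labelled)
    out["n_labelled"] = float(len(labelled))
    return out


def progenitor_comparison(
    wheat_counts: pd.DataFrame, progenitor_counts: pd.DataFrame
) -> pd.DataFrame:
    """Tally copy-number changes of genes versus progenitor orthologs.

    Both frames are gene × comparison (columns = genome comparisons, values =
    copy numbers).  Genes missing a progenitor entry (NaN) are skipped for
    that comparison.  Returns per-comparison counts and percentages of
    lower/greater/equal copy number, plus an ``average`` row of the mean
    per-comparison tallies.
    """
    comparisons = [c for c in wheat_counts.columns if c in progenitor_counts.columns]
    if not comparisons:
        raise ValueError("no shared genome comparisons")
    rows = []
    for comp in comparisons:
        joined = pd.concat(
            [wheat_counts[comp].rename("wheat"), progenitor_counts[comp].rename("prog")],
            axis=1,
        ).dropna()
        diff = np.sign(joined["wheat"] - joined["prog"])
        n = len(joined)
        lower = int((diff < 0).sum())
        greater = int((diff > 0).sum())
        equal = int((diff == 0).sum())
        rows.append((comp, n, lower, greater, equal))
    frame = pd.DataFrame(rows, columns=["comparison", "n", "lower", "greater", "equal"])
    avg = frame[["n", "lower", "greater", "equal"]].mean()
    frame = pd.concat(
        [frame, pd.DataFrame([["average", *avg.tolist()]], columns=frame.columns)],
        ignore_index=True,
    )
    for col in ("lower", "greater", "equal"):
        frame[f"{col}_pct"] = 100.0 * frame[col] / frame["n"]
    return frame


def assign_compartment(
    chromosome: str, position: int, compartments: CompartmentTable
) -> str:
    """Genomic compartment containing ``position`` (0-based, half-open)."""
    if position < 0:
        raise ValueError("position must be >= 0")
    frame = compartments.frame
    if chromosome not in set(frame["chromosome"]):
        raise KeyError(f"chromosome {chromosome!r} not in compartment table")
    chrom = frame[frame["chromosome"] == chromosome]
    hit = chrom[(chrom["start"] <= position) & (position < chrom["end"])]
    if len(hit) == 0:
        return "unassigned"
    return str(hit["label"].iloc[0])


def classify_triads_in_tissue(
    tpm: ExpressionMatrix,
    samples: SampleTable,
    homeologs,
    tissue: str,
    aggregate: str = "mean",
) -> list[TriadContribution]:
    """Classify every 1:1:1 triad's expression bias in one tissue.

    TPM is averaged over the tissue's samples first, then turned into
    contributions.  Triads with zero total expression, or with a member
    absent from the matrix, are excluded.
    """
    means = mean_tissue_tpm(tpm, samples, tissue, aggregate)
    copy_numbers = homeologs.copy_numbers()
    triad_ids = copy_numbers.index[
        (copy_numbers["nA"] == 1) & (copy_numbers["nB"] == 1) & (copy_numbers["nD"] == 1)
    ]
    out: list[TriadContribution] = []
    frame = homeologs.frame
    for triad_id in triad_ids:
        members = frame[frame["group_id"] == triad_id].set_index("subgenome")["gene_id"]
        genes = [members.get(g) for g in ("A", "B", "D")]
        if any(g is None or g not in means.index for g in genes):
            continue
        t = [float(means[g]) for g in genes]
        if sum(t) <= 0:
            continue
        contribs = relative_contributions(*t)
        category, dists = classify_triad(contribs)
        out.append(TriadContribution(str(triad_id), *contribs, category, dists))
    return out
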