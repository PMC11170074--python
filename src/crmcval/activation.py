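"""Tissue-specific functional-state transfer, clustering, activity breadth.

Per-tissue activation probabilities predicted for CRMCs are transferred
to validated elements through a reciprocal-overlap rule (default 50%,
inclusive): an element inherits states from every CRMC whose overlap
with it is at least the threshold fraction of *both* lengths. When
several CRMCs qualify, their probabilities are combined — by default the
maximum (an element containing any active CRMC is plausibly active); an
overlap-length-weighted mean is available. Elements with no qualifying
CRMC get missing rows and are reported, never silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genomic_io import Crmc, GenomicInterval, ValidatedElement, interval_overlap

logger = logging.getLogger(__name__)

COMBINE_RULES = ("max", "length_weighted_mean")


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval, threshold: float = 0.5
) -> bool:
    """True iff the overlap is >= threshold of both interval lengths (inclusive)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    ov = interval_overlap(a, b)
    return ov >= threshold * a.length() and ov >= threshold * b.length()


@dataclass
class ActivationMatrix:
    """Elements x tissues activation probabilities with binary active calls."""

    probs: pd.DataFrame  # index element ids; NaN rows = no qualifying CRMC
    labels: pd.Series  # element id -> VPR/VNR
    t_active: float
    no_match: list[str] = field(default_factory=list)

    @property
    def binary(self) -> pd.DataFrame:
        return (self.probs > self.t_active).where(~self.probs.isna())

    def complete(self) -> "ActivationMatrix":
        """Copy restricted to elements that received states."""
        keep = self.probs.dropna().index
        return ActivationMatrix(
            self.probs.loc[keep], self.labels.loc[keep], self.t_active, []
        )


def transfer_states(
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    states: pd.DataFrame,
    *,
    threshold: float = 0.5,
    combine: str = "max",
    t_active: float = 0.5,
) -> ActivationMatrix:
    """Transfer per-tissue CRMC activation probabilities to elements.

    ``states`` has CRMC ids as index and tissue names as columns, values
    in [0, 1]. A qualifying CRMC absent from ``states`` is an error
    naming the CRMC.
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"unknown combine rule {combine!r}")
    if states.index.has_duplicates or states.columns.has_duplicates:
        raise ValueError("duplicate CRMC ids or tissue names in state table")
    vals = states.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ValueError("activation probabilities must lie in [0, 1]")
    rows = {}
    no_match = []
    for el in elements:
        qual = [c for c in crmcs if reciprocal_overlap(el.interval, c.interval, threshold)]
        if not qual:
            rows[el.id] = np.full(states.shape[1], np.nan)
            no_match.append(el.id)
            continue
        missing = [c.id for c in qual if c.id not in states.index]
        if missing:
            raise KeyError(f"qualifying CRMC {missing[0]} absent from the state table")
        mat = states.loc[[c.id for c in qual]].to_numpy(dtype=float)
        if combine == "max":
            rows[el.id] = mat.max(axis=0)
        else:
            w = np.array(
                [interval_overlap(el.interval, c.interval) for c in qual], dtype=float
            )
            rows[el.id] = (mat * w[:, None]).sum(axis=0) / w.sum()
    if no_match:
        logger.info(
            "%d elements had no CRMC at %.0f%% reciprocal overlap: %s",
            len(no_match), 100 * threshold, ", ".join(no_match[:10]),
        )
    probs = pd.DataFrame.from_dict(rows, orient="index", columns=states.columns)
    probs = probs.loc[[el.id for el in elements]]
    labels = pd.Series({el.id: el.label for el in elements}).loc[probs.index]
    return ActivationMatrix(probs, labels, t_active, no_match)


@dataclass
class TwoWayClustering:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray = field(repr=False, default=None)
    col_linkage: np.ndarray = field(repr=False, default=None)


def cluster_two_way(
    matrix: ActivationMatrix,
    *,
    linkage: str = "average",
    metric: str = "euclidean",
) -> TwoWayClustering:
    """Hierarchical agglomerative clustering of rows and of columns.

    Rows with missing values (elements without a qualifying CRMC) are
    dropped with a warning. Leaf orders are deterministic given the input
    order. Defaults — Euclidean distance, average linkage, no
    standardization — are common heatmap conventions.
    """
    probs = matrix.probs.dropna()
    n_dropped = len(matrix.probs) - len(probs)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with missing states before clustering")
    if probs.shape[0] < 2 or probs.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    X = probs.to_numpy(dtype=float)
    row_link = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    col_link = hierarchy.linkage(pdist(X.T, metric=metric), method=linkage)
    row_order = [probs.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [probs.columns[i] for i in hierarchy.leaves_list(col_link)]
    return TwoWayClustering(row_order, col_order, row_link, col_link)


@dataclass
class BreadthSummary:
    """Per-class activity breadth: 'active in k tissues' statistics."""

    k_histogram: dict[str, dict[int, int]]  # class -> {k: count}
    per_tissue_counts: pd.DataFrame  # tissues x classes
    fraction_active: dict[str, float]  # class -> fraction with k >= 1
    n_elements: dict[str, int]


def activity_breadth(matrix: ActivationMatrix) -> BreadthSummary:
    """Distribution of the number of tissues each element is active in.

    Elements without transferred states (missing rows) are excluded; the
    counts are over elements with binary calls at ``t_active``.
    """
    binary = matrix.binary.dropna().astype(bool)
    labels = matrix.labels.loc[binary.index]
    n_tissues = binary.shape[1]
    k_hist: dict[str, dict[int, int]] = {}
    frac: dict[str, float] = {}
    n_el: dict[str, int] = {}
    tissue_counts = {}
    for cls in ("VPR", "VNR"):
        sub = binary.loc[labels == cls]
        ks = sub.sum(axis=1).astype(int)
        k_hist[cls] = {k: int((ks == k).sum()) for k in range(n_tissues + 1)}
        n_el[cls] = len(sub)
        frac[cls] = float((ks >= 1).mean()) if len(sub) else float("nan")
        tissue_counts[cls] = sub.sum(axis=0).astype(int)
    per_tissue = pd.DataFrame(tissue_counts)
    return BreadthSummary(k_hist, per_tissue, frac, n_el)
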