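"""Base-level partition of recalled elements vs recalling CRMCs.

Positions covered by recalled validated elements and by their recalling
CRMCs are partitioned into three classes — shared, CRMC-specific and
element-specific — and the conservation-score distributions of the
classes are contrasted. "Recalling CRMCs" here means *all* CRMCs passing
the cutoff that satisfy the overlap rule for some recalled element, not
just the single credited one: the partition is about sequence coverage,
and restricting to one CRMC per element would misclassify covered bases
as element-specific. Every base counts once, even under multiple
features; non-recalled elements contribute no positions.

Length ratios, by contrast, use the single credited recalling CRMC per
element (the pairwise max-overlap choice), since the ratio is defined per
recalled pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_io import (
    ConservationTrack,
    Crmc,
    GenomicInterval,
    ValidatedElement,
    intersect_sets,
    merge_intervals,
    subtract_sets,
    total_bp,
)
from .recall import RecallResult, eligible_overlapping

logger = logging.getLogger(__name__)

DEFAULT_BINS = np.round(np.arange(-3.0, 6.0 + 1e-9, 0.1), 10)


@dataclass
class PositionPartition:
    shared_bp: int
    crmc_specific_bp: int
    element_specific_bp: int
    shared_intervals: list[GenomicInterval] = field(repr=False, default_factory=list)
    crmc_specific_intervals: list[GenomicInterval] = field(repr=False, default_factory=list)
    element_specific_intervals: list[GenomicInterval] = field(repr=False, default_factory=list)

    @property
    def total_element_bp(self) -> int:
        return self.shared_bp + self.element_specific_bp

    @property
    def total_crmc_bp(self) -> int:
        return self.shared_bp + self.crmc_specific_bp

    def score_samples(self, track: ConservationTrack) -> dict[str, np.ndarray]:
        """Conservation values per class, missing positions dropped."""
        return {
            "shared": track.values(self.shared_intervals),
            "crmc_specific": track.values(self.crmc_specific_intervals),
            "element_specific": track.values(self.element_specific_intervals),
        }


@dataclass
class ScoreDistribution:
    sample: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray


@dataclass
class LengthRatioSummary:
    ratios: np.ndarray  # recalling CRMC length / element length, per recalled element

    @property
    def mean(self) -> float:
        return float(np.mean(self.ratios)) if self.ratios.size else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.ratios)) if self.ratios.size else float("nan")

    @property
    def quartiles(self) -> tuple[float, float]:
        if not self.ratios.size:
            return (float("nan"), float("nan"))
        q1, q3 = np.percentile(self.ratios, [25, 75])
        return (float(q1), float(q3))


def partition_positions(
    recall: RecallResult,
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    *,
    track: ConservationTrack | None = None,
) -> PositionPartition:
    """Partition bases of recalled elements and their recalling CRMCs.

    shared = union(recalled elements) ∩ union(recalling CRMCs);
    element-specific = element bases outside that CRMC union;
    CRMC-specific = recalling-CRMC bases outside the element union.
    Zero recalled elements yield an all-zero partition.
    """
    by_id = {el.id: el for el in elements}
    recalled = [by_id[e] for e in recall.element_ids if recall.recalling[e] is not None]
    if not recalled:
        return PositionPartition(0, 0, 0)
    hits = eligible_overlapping(
        recalled,
        crmcs,
        recall.cutoff,
        min_overlap_bp=recall.min_overlap_bp,
        reciprocal=recall.reciprocal,
    )
    recalling_ids: set[str] = set()
    for el in recalled:
        recalling_ids.update(c.id for c in hits[el.id])
    e_union = merge_intervals([el.interval for el in recalled])
    c_union = merge_intervals([c.interval for c in crmcs if c.id in recalling_ids])
    shared = intersect_sets(e_union, c_union)
    el_spec = subtract_sets(e_union, c_union)
    cr_spec = subtract_sets(c_union, e_union)
    part = PositionPartition(
        total_bp(shared), total_bp(cr_spec), total_bp(el_spec), shared, cr_spec, el_spec
    )
    assert part.shared_bp + part.element_specific_bp == total_bp(e_union)
    assert part.shared_bp + part.crmc_specific_bp == total_bp(c_union)
    n_multi = sum(1 for el in recalled if len(hits[el.id]) > 1)
    if n_multi:
        logger.info("%d recalled elements overlap more than one recalling CRMC", n_multi)
    return part


def score_distribution(
    intervals: list[GenomicInterval],
    track: ConservationTrack,
    bins: np.ndarray | None = None,
) -> ScoreDistribution:
    """Histogram + raw sample of conservation scores over an interval set.

    Missing positions are dropped; values beyond the outer bin edges fall
    into open-ended tail bins. An all-missing input is an error.
    """
    sample = track.values(intervals)
    if sample.size == 0:
        raise ValueError("all positions missing from the conservation track")
    edges = DEFAULT_BINS if bins is None else np.asarray(bins, dtype=float)
    full_edges = np.concatenate(([-np.inf], edges, [np.inf]))
    counts, _ = np.histogram(sample, bins=full_edges)
    return ScoreDistribution(sample, counts, full_edges)


def compare_distributions(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test; returns (D, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values for the K-S test")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def length_ratios(
    recall: RecallResult,
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
) -> LengthRatioSummary:
    """Per recalled element, (credited recalling CRMC length) / (element length)."""
    el_by_id = {el.id: el for el in elements}
    crmc_by_id = {c.id: c for c in crmcs}
    ratios = []
    for el_id in recall.element_ids:
        crmc_id = recall.recalling[el_id]
        if crmc_id is None:
            continue
        ratios.append(
            crmc_by_id[crmc_id].interval.length() / el_by_id[el_id].interval.length()
        )
    return LengthRatioSummary(np.asarray(ratios, dtype=float))
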