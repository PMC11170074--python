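"""Element recall by predicted CRMCs and the length-matched control null.

A validated element is *recalled* at a p-value cutoff when at least one
CRMC passing the cutoff overlaps it by ``min_overlap_bp`` (default 1 bp —
the weakest rule, which reproduces near-total recall of validated regions
by dense CRMC predictions; stricter rules, including a reciprocal-overlap
mode, are configurable). The credited *recalling* CRMC is the eligible
CRMC with maximum overlap, ties broken by smaller p-value, then leftmost
start, then id.

The null model re-places every CRMC as a random segment of identical
length uniformly inside the TF-peak-covered regions; controls inherit
their CRMC's p-value and may overlap one another or real CRMCs, since
excluding them would bias the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import Crmc, GenomicInterval, ValidatedElement, interval_overlap
from .synthetic import substream


@dataclass
class RecallResult:
    cutoff: float
    min_overlap_bp: int
    element_ids: tuple[str, ...]
    recalling: dict[str, str | None]  # element id -> recalling CRMC id
    reciprocal: float | None = None

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    @property
    def n_recalled(self) -> int:
        return sum(1 for v in self.recalling.values() if v is not None)

    @property
    def sensitivity(self) -> float:
        return self.n_recalled / self.n_elements

    def recalled_flags(self) -> np.ndarray:
        return np.array([self.recalling[e] is not None for e in self.element_ids])


@dataclass
class Chi2Result:
    statistic: float
    p_value: float
    df: int
    table: list[list[int]]
    degenerate: bool = False


@dataclass
class SensitivityCurve:
    cutoffs: tuple[float, ...]
    crmc_sensitivity: tuple[float, ...]
    control_sensitivity: tuple[float, ...]
    crmc_results: list[RecallResult] = field(repr=False, default_factory=list)
    control_results: list[RecallResult] = field(repr=False, default_factory=list)
    chi2: list[Chi2Result] = field(repr=False, default_factory=list)


def _trees(crmcs: list[Crmc]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in crmcs:
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, c
        )
    return trees


def eligible_overlapping(
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    cutoff: float,
    *,
    min_overlap_bp: int = 1,
    reciprocal: float | None = None,
) -> dict[str, list[Crmc]]:
    """Per element, all CRMCs passing the cutoff that satisfy the overlap rule."""
    eligible = [c for c in crmcs if c.p_value <= cutoff]
    trees = _trees(eligible)
    out: dict[str, list[Crmc]] = {}
    for el in elements:
        hits = []
        tree = trees.get(el.interval.chrom)
        if tree is not None:
            for node in tree.overlap(el.interval.start, el.interval.end):
                c: Crmc = node.data
                ov = interval_overlap(el.interval, c.interval)
                if ov < min_overlap_bp:
                    continue
                if reciprocal is not None and (
                    ov < reciprocal * el.interval.length()
                    or ov < reciprocal * c.interval.length()
                ):
                    continue
                hits.append(c)
        hits.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.id))
        out[el.id] = hits
    return out


def recall_elements(
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    cutoff: float,
    *,
    min_overlap_bp: int = 1,
    reciprocal: float | None = None,
) -> RecallResult:
    """Recall flags and recalling-CRMC assignment at one p-value cutoff."""
    if not elements:
        raise ValueError("empty element list")
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    hits = eligible_overlapping(
        elements, crmcs, cutoff, min_overlap_bp=min_overlap_bp, reciprocal=reciprocal
    )
    recalling: dict[str, str | None] = {}
    for el in elements:
        cands = hits[el.id]
        if not cands:
            recalling[el.id] = None
            continue
        best = min(
            cands,
            key=lambda c: (
                -interval_overlap(el.interval, c.interval),
                c.p_value,
                c.interval.start,
                c.id,
            ),
        )
        recalling[el.id] = best.id
    return RecallResult(
        cutoff, min_overlap_bp, tuple(e.id for e in elements), recalling, reciprocal
    )


def sample_controls(
    crmcs: list[Crmc],
    covered: list[GenomicInterval],
    seed: int,
) -> list[Crmc]:
    """One random length-matched control per CRMC, uniform over covered regions.

    A control of length L is placed uniformly over *all* start positions
    such that it lies wholly inside one covered segment. Controls inherit
    their CRMC's p-value; draws are deterministic under the seed.
    """
    rng = substream(seed, "controls")
    seg_lengths = np.array([seg.length() for seg in covered], dtype=np.int64)
    controls = []
    for c in crmcs:
        L = c.interval.length()
        feasible = np.maximum(0, seg_lengths - L + 1)
        total = int(feasible.sum())
        if total == 0:
            raise ValueError(
                f"CRMC {c.id} (length {L}) is longer than every covered segment"
            )
        r = int(rng.integers(total))
        cum = np.cumsum(feasible)
        j = int(np.searchsorted(cum, r, side="right"))
        offset = r - (int(cum[j - 1]) if j > 0 else 0)
        seg = covered[j]
        iv = GenomicInterval(seg.chrom, seg.start + offset, seg.start + offset + L)
        controls.append(Crmc(iv, f"ctl_{c.id}", c.p_value))
    return controls


def compare_sensitivity(result_a: RecallResult, result_b: RecallResult) -> Chi2Result:
    """Chi-square test on the 2x2 recalled-by table (no continuity correction).

    The two results must cover the same element set. A zero margin (e.g.
    everything recalled by both) makes the test undefined; the result is
    flagged degenerate instead.
    """
    if set(result_a.element_ids) != set(result_b.element_ids):
        raise ValueError("recall results cover different element sets")
    a_rec, b_rec = result_a.n_recalled, result_b.n_recalled
    table = [
        [a_rec, result_a.n_elements - a_rec],
        [b_rec, result_b.n_elements - b_rec],
    ]
    margins = [a_rec + b_rec, table[0][1] + table[1][1]]
    if 0 in margins:
        return Chi2Result(float("nan"), float("nan"), 1, table, degenerate=True)
    res = stats.chi2_contingency(np.array(table), correction=False)
    return Chi2Result(float(res.statistic), float(res.pvalue), 1, table)


def sensitivity_curve(
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    covered: list[GenomicInterval],
    cutoffs: list[float],
    seed: int,
    *,
    min_overlap_bp: int = 1,
    reciprocal: float | None = None,
) -> SensitivityCurve:
    """Recall sensitivity of CRMCs and of one control draw across cutoffs.

    Controls are drawn once per curve (not per cutoff) and re-thresholded
    at each cutoff via their inherited p-values. CRMC sensitivity is
    checked to be non-decreasing in the cutoff.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    controls = sample_controls(crmcs, covered, seed)
    crmc_res, ctl_res, chi2s = [], [], []
    for cut in cutoffs:
        r = recall_elements(
            elements, crmcs, cut, min_overlap_bp=min_overlap_bp, reciprocal=reciprocal
        )
        s = recall_elements(
            elements, controls, cut, min_overlap_bp=min_overlap_bp, reciprocal=reciprocal
        )
        crmc_res.append(r)
        ctl_res.append(s)
        chi2s.append(compare_sensitivity(r, s))
    sens = [r.sensitivity for r in crmc_res]
    assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:])), (
        "CRMC sensitivity must be non-decreasing in the cutoff"
    )
    return SensitivityCurve(
        tuple(cutoffs),
        tuple(sens),
        tuple(s.sensitivity for s in ctl_res),
        crmc_res,
        ctl_res,
        chi2s,
    )


def random_placement_hit_rate(
    elements: list[ValidatedElement],
    crmcs: list[Crmc],
    covered: list[GenomicInterval],
) -> float:
    """Analytic expected control sensitivity under uniform random placement.

    For each element, the probability that at least one of the
    independently placed length-matched controls overlaps it is computed
    by exact enumeration of feasible placements per covered segment. The
    mean over elements is the expected control sensitivity at cutoff 1.0.
    """
    seg = [(s.chrom, s.start, s.end, s.length()) for s in covered]
    lengths = [c.interval.length() for c in crmcs]
    totals = {}
    for L in set(lengths):
        totals[L] = sum(max(0, sl - L + 1) for _, _, _, sl in seg)
    p_any = []
    for el in elements:
        log_miss = 0.0
        for L in lengths:
            hit = 0
            for chrom, s0, e0, sl in seg:
                if chrom != el.interval.chrom:
                    continue
                # control start t in [s0, e0 - L]; overlap iff t + L > start and t < end
                lo = max(s0, el.interval.start - L + 1)
                hi = min(e0 - L, el.interval.end - 1)
                if hi >= lo:
                    hit += hi - lo + 1
            p_hit = hit / totals[L] if totals[L] > 0 else 0.0
            log_miss += np.log1p(-min(p_hit, 1.0 - 1e-15))
        p_any.append(1.0 - np.exp(log_miss))
    return float(np.mean(p_any))
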