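"""In-silico saturation-mutagenesis impact profiles and conservation overlay.

For every validated element a fixed-size window (default 2000 bp) is
anchored at the element midpoint; a pluggable variant scorer assigns
per-feature effect scores to each of the three possible substitutions at
each window position. The per-position impact is the maximum over the
three alternative alleles of the aggregated absolute feature scores
(feature aggregation defaults to the mean of absolute values; max is
available). Profiles average these impacts per offset across elements of
a class, and are correlated with the per-offset mean absolute
conservation score after removing evolutionarily neutral offsets.

The scorer seam accepts any callable ``scorer(window, position, alt) ->
feature vector``; scorers exposing a vectorised ``score_window(window)``
returning a ``(window_size, 3, n_features)`` tensor (such as the
synthetic scorer, or the TSV-backed scorer that ingests external model
exports) are used in bulk for speed, with identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import ConservationTrack, GenomeManifest, GenomicInterval, ValidatedElement

logger = logging.getLogger(__name__)

#: per-offset mean |phyloP| below which positions count as neutral
NEUTRAL_THRESHOLDS = {"human": 1.0, "mouse": 0.7}

FEATURE_AGGS = ("mean", "max")


@dataclass(frozen=True)
class MutWindow:
    element_id: str
    interval: GenomicInterval
    sequence: str | None = None

    def offsets(self) -> np.ndarray:
        W = self.interval.length()
        return np.arange(W) - W // 2


@dataclass
class ImpactProfile:
    offsets: np.ndarray
    mean_impact: np.ndarray  # NaN where no window contributed
    counts: np.ndarray

    @property
    def window_size(self) -> int:
        return len(self.offsets)


@dataclass
class ConservationProfile:
    offsets: np.ndarray
    mean_abs_score: np.ndarray  # NaN where every window was missing
    counts: np.ndarray


def extract_window(
    element: ValidatedElement,
    manifest: GenomeManifest,
    *,
    window_size: int = 2000,
    sequences=None,
) -> MutWindow | None:
    """Midpoint-anchored window around one element, or None when clipped.

    The window is ``[mid - W//2, mid + W//2)`` with ``mid = floor((start +
    end)/2)``: elements shorter than W gain flanking context, longer ones
    are represented by their central W bases. Windows running past a
    chromosome end are skipped with a log record.
    """
    if element.interval.chrom not in manifest.lengths:
        raise KeyError(f"chromosome {element.interval.chrom} absent from manifest")
    mid = element.interval.midpoint()
    w0 = mid - window_size // 2
    w1 = w0 + window_size
    if w0 < 0 or w1 > manifest.lengths[element.interval.chrom]:
        logger.info(
            "skipping element %s: window [%d, %d) outside chromosome %s",
            element.id, w0, w1, element.interval.chrom,
        )
        return None
    seq = None
    if sequences is not None:
        seq = str(sequences[element.interval.chrom][w0:w1]).upper()
    return MutWindow(element.id, GenomicInterval(element.interval.chrom, w0, w1), seq)


def extract_windows(
    elements, manifest, *, window_size: int = 2000, sequences=None
) -> list[MutWindow]:
    out = []
    for el in elements:
        w = extract_window(el, manifest, window_size=window_size, sequences=sequences)
        if w is not None:
            out.append(w)
    return out


def _agg(abs_features: np.ndarray, feature_agg: str, axis: int = -1) -> np.ndarray:
    if feature_agg == "mean":
        return abs_features.mean(axis=axis)
    if feature_agg == "max":
        return abs_features.max(axis=axis)
    raise ValueError(f"unknown feature aggregation {feature_agg!r}")


def position_impact(
    scorer, window: MutWindow, position: int, feature_agg: str = "mean"
) -> float:
    """Impact at one window position: max over the 3 alternative alleles.

    Each allele's per-feature scores are taken in absolute value and
    aggregated across features; the position's impact is the maximum of
    the three allele values. Ambiguous reference bases (N) are skipped
    (NaN returned) with a log record.
    """
    if window.sequence is None:
        raise ValueError("position_impact requires a window with reference sequence")
    if not (0 <= position < window.interval.length()):
        raise ValueError(f"position {position} outside window")
    ref = window.sequence[position].upper()
    if ref not in "ACGT":
        logger.info("skipping ambiguous reference base %r in %s", ref, window.element_id)
        return float("nan")
    per_allele = []
    for alt in (b for b in "ACGT" if b != ref):
        feats = np.abs(np.asarray(scorer(window, position, alt), dtype=float))
        per_allele.append(float(_agg(feats, feature_agg)))
    return max(per_allele)


def _window_impacts(scorer, window: MutWindow, feature_agg: str) -> np.ndarray:
    """Per-position impacts for one window, using the bulk path if offered."""
    W = window.interval.length()
    if hasattr(scorer, "score_window"):
        tensor = np.asarray(scorer.score_window(window), dtype=float)  # (W, 3, F)
        imp = _agg(np.abs(tensor), feature_agg, axis=2).max(axis=1)
        if window.sequence is not None:
            mask = np.frombuffer(window.sequence.encode(), dtype="S1")
            ambiguous = ~np.isin(mask, np.frombuffer(b"ACGT", dtype="S1"))
            if ambiguous.any():
                imp = imp.copy()
                imp[ambiguous] = np.nan
        return imp
    return np.array(
        [position_impact(scorer, window, pos, feature_agg) for pos in range(W)]
    )


def average_profile(
    windows: list[MutWindow], scorer, feature_agg: str = "mean"
) -> ImpactProfile:
    """Mean per-offset impact across windows (skipped positions excluded)."""
    if not windows:
        raise ValueError("at least one window is required")
    W = windows[0].interval.length()
    if any(w.interval.length() != W for w in windows):
        raise ValueError("windows must share one window size")
    mat = np.vstack([_window_impacts(scorer, w, feature_agg) for w in windows])
    counts = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        means = np.where(counts > 0, np.nanmean(mat, axis=0), np.nan)
    return ImpactProfile(windows[0].offsets(), means, counts)


def per_window_mean_impact(
    windows: list[MutWindow], scorer, feature_agg: str = "mean"
) -> np.ndarray:
    """Mean impact over all positions of each window (one value per window)."""
    return np.array(
        [float(np.nanmean(_window_impacts(scorer, w, feature_agg))) for w in windows]
    )


def conservation_profile(
    windows: list[MutWindow], track: ConservationTrack
) -> ConservationProfile:
    """Per-offset mean of |conservation| across windows, missing-aware."""
    if not windows:
        raise ValueError("at least one window is required")
    W = windows[0].interval.length()
    mat = np.vstack([np.abs(track.slice(w.interval)) for w in windows])
    counts = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        means = np.where(counts > 0, np.nanmean(mat, axis=0), np.nan)
    return ConservationProfile(windows[0].offsets(), means, counts)


def impact_conservation_correlation(
    impact: ImpactProfile,
    cons: ConservationProfile,
    neutral_threshold: float,
) -> tuple[float, int]:
    """Pearson r between per-offset impact and |conservation| means.

    Offsets whose mean absolute conservation falls below the neutral
    threshold are removed first (thresholds 1.0/0.7 are shipped as the
    human/mouse presets in :data:`NEUTRAL_THRESHOLDS`). Returns (r, number
    of offsets retained); fewer than 3 retained offsets is an error.
    """
    if len(impact.offsets) != len(cons.offsets) or np.any(impact.offsets != cons.offsets):
        raise ValueError("impact and conservation profiles must share offsets")
    keep = (
        np.isfinite(impact.mean_impact)
        & np.isfinite(cons.mean_abs_score)
        & (cons.mean_abs_score >= neutral_threshold)
    )
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"only {n} offsets retained after neutral filtering")
    r, _ = stats.pearsonr(impact.mean_impact[keep], cons.mean_abs_score[keep])
    return float(r), n


class TsvVariantScorer:
    """Scorer backed by an external model's exported scores.

    Expects a TSV with columns (element_id, offset, alt_allele, feature,
    score), offsets relative to the window midpoint; rows missing for a
    (position, allele) score as 0. This lets real variant-effect model
    exports drive the same profile machinery as the synthetic scorer.
    """

    def __init__(self, path):
        df = pd.read_csv(
            path, sep="\t",
            names=["element_id", "offset", "alt_allele", "feature", "score"],
            header=0,
        )
        self.features = sorted(df["feature"].unique())
        self._groups = {k: g for k, g in df.groupby("element_id")}

    def score_window(self, window: MutWindow) -> np.ndarray:
        W = window.interval.length()
        half = W // 2
        tensor = np.zeros((W, 3, len(self.features)))
        g = self._groups.get(window.element_id)
        if g is None:
            return tensor
        feat_idx = {f: i for i, f in enumerate(self.features)}
        if window.sequence is None:
            raise ValueError("TSV scorer needs window sequences to index alleles")
        for row in g.itertuples(index=False):
            pos = int(row.offset) + half
            if not (0 <= pos < W):
                continue
            ref = window.sequence[pos].upper()
            alts = [b for b in "ACGT" if b != ref]
            if row.alt_allele not in alts:
                continue
            tensor[pos, alts.index(row.alt_allele), feat_idx[row.feature]] = row.score
        return tensor

    def __call__(self, window: MutWindow, position: int, alt: str) -> np.ndarray:
        ref = window.sequence[position].upper()
        alts = [b for b in "ACGT" if b != ref]
        if alt not in alts:
            raise ValueError(f"invalid alt allele {alt!r}")
        return self.score_window(window)[position, alts.index(alt)]
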