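"""Genomic interval primitives and flat-file I/O.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; any 1-based coordinate appears only in log messages. Strand is
ignored throughout: validated elements and CRM candidates are treated as
unstranded regions.

Conservation score tracks use phyloP semantics: positive values indicate
purifying selection, negative values acceleration, values near zero
neutrality. Positions without a score are stored as NaN and are *excluded*
(never zero-filled) from every downstream distribution, since a missing
phyloP value carries no evidence of neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_LABELS = ("VPR", "VNR")


class BedFormatError(ValueError):
    """Malformed BED/bedGraph input; the message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A region ``[start, end)`` on ``chrom``, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 if on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Crmc:
    """A predicted cis-regulatory module candidate with its prediction p-value."""

    interval: GenomicInterval
    id: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"CRMC {self.id}: p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class ValidatedElement:
    """A validated region from an enhancer assay, labelled VPR or VNR."""

    interval: GenomicInterval
    id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"element {self.id}: unknown label {self.label!r}; "
                f"expected one of {VALID_LABELS}"
            )


@dataclass
class GenomeManifest:
    """Ordered chromosome names and lengths, optionally with a FASTA path."""

    chroms: list[tuple[str, int]]
    fasta: Path | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in manifest")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def order_index(self, chrom: str) -> int:
        return self.names.index(chrom)

    def contains(self, iv: GenomicInterval) -> bool:
        length = self.lengths.get(iv.chrom)
        return length is not None and iv.end <= length

    def total_bp(self) -> int:
        return sum(length for _, length in self.chroms)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeManifest":
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise BedFormatError(f"{path}:{lineno}: expected 'name length'")
                chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chroms:
                fh.write(f"{name}\t{length}\n")


class ConservationTrack:
    """Dense per-base conservation scores per chromosome (NaN = missing)."""

    def __init__(self, scores: dict[str, np.ndarray], manifest: GenomeManifest):
        for name, length in manifest.chroms:
            if name not in scores:
                raise ValueError(f"track missing chromosome {name}")
            if len(scores[name]) != length:
                raise ValueError(
                    f"track length {len(scores[name])} != manifest length "
                    f"{length} for chromosome {name}"
                )
        self.scores = {name: np.asarray(scores[name], dtype=float) for name, _ in manifest.chroms}
        self.manifest = manifest

    @classmethod
    def empty(cls, manifest: GenomeManifest) -> "ConservationTrack":
        return cls(
            {name: np.full(length, np.nan) for name, length in manifest.chroms},
            manifest,
        )

    def slice(self, iv: GenomicInterval) -> np.ndarray:
        if iv.chrom not in self.scores:
            raise KeyError(f"chromosome {iv.chrom} not in track")
        if not self.manifest.contains(iv):
            raise ValueError(f"interval {iv} beyond chromosome length")
        return self.scores[iv.chrom][iv.start : iv.end]

    def values(
        self, intervals: Iterable[GenomicInterval], drop_missing: bool = True
    ) -> np.ndarray:
        parts = [self.slice(iv) for iv in intervals]
        out = np.concatenate(parts) if parts else np.empty(0)
        if drop_missing:
            out = out[~np.isnan(out)]
        return out

    def n_covered(self) -> int:
        return int(sum(np.count_nonzero(~np.isnan(a)) for a in self.scores.values()))


# ---------------------------------------------------------------------------
# BED reading / writing
# ---------------------------------------------------------------------------

def _interval_of(fields: Sequence[str], path, lineno) -> GenomicInterval:
    try:
        return GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
    except (ValueError, IndexError) as exc:
        raise BedFormatError(f"{path}:{lineno}: {exc}") from None


def read_bed(
    path: str | Path,
    kind: str = "plain",
    *,
    id_column: int = 4,
    p_value_column: int = 5,
    label_column: int = 6,
):
    """Read a BED file as plain intervals, CRMCs or validated elements.

    Column indices are 1-based over the tab-separated BED columns, so the
    defaults follow BED6: name in column 4, score (carrying the CRMC
    p-value) in column 5, and the VPR/VNR label in column 6. Exports from
    different databases can remap any of them. Input order is preserved.
    """
    if kind not in ("plain", "crmc", "element"):
        raise ValueError(f"unknown kind {kind!r}")
    records = []
    ids_seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            iv = _interval_of(fields, path, lineno)
            if kind == "plain":
                records.append(iv)
                continue
            try:
                rec_id = fields[id_column - 1]
            except IndexError:
                raise BedFormatError(
                    f"{path}:{lineno}: missing id column {id_column}"
                ) from None
            if rec_id in ids_seen:
                raise BedFormatError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            ids_seen.add(rec_id)
            if kind == "crmc":
                try:
                    p = float(fields[p_value_column - 1])
                except (IndexError, ValueError):
                    raise BedFormatError(
                        f"{path}:{lineno}: missing or non-numeric p-value "
                        f"in column {p_value_column}"
                    ) from None
                try:
                    records.append(Crmc(iv, rec_id, p))
                except ValueError as exc:
                    raise BedFormatError(f"{path}:{lineno}: {exc}") from None
            else:  # element
                try:
                    label = fields[label_column - 1]
                except IndexError:
                    raise BedFormatError(
                        f"{path}:{lineno}: missing label column {label_column}"
                    ) from None
                try:
                    records.append(ValidatedElement(iv, rec_id, label))
                except ValueError as exc:
                    raise BedFormatError(f"{path}:{lineno}: {exc}") from None
    return records


def _bed_fields(rec) -> list[str]:
    if isinstance(rec, ValidatedElement):
        iv = rec.interval
        return [iv.chrom, str(iv.start), str(iv.end), rec.id, "0", rec.label]
    if isinstance(rec, Crmc):
        iv = rec.interval
        return [iv.chrom, str(iv.start), str(iv.end), rec.id, repr(rec.p_value)]
    if isinstance(rec, GenomicInterval):
        return [rec.chrom, str(rec.start), str(rec.end)]
    raise TypeError(f"cannot write record of type {type(rec).__name__}")


def write_bed(
    records: Iterable,
    path: str | Path,
    *,
    manifest: GenomeManifest | None = None,
    sort: bool = False,
) -> None:
    """Write records in the same BED dialect ``read_bed`` expects.

    With ``sort=True`` records are ordered by (chromosome, start); the
    chromosome order follows the manifest when one is given, lexicographic
    order otherwise.
    """
    records = list(records)
    if sort:
        if manifest is not None:
            order = {name: i for i, name in enumerate(manifest.names)}
            key = lambda r: (order[_iv(r).chrom], _iv(r).start, _iv(r).end)
        else:
            key = lambda r: (_iv(r).chrom, _iv(r).start, _iv(r).end)
        records = sorted(records, key=key)
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(_bed_fields(rec)) + "\n")


def _iv(rec) -> GenomicInterval:
    return rec if isinstance(rec, GenomicInterval) else rec.interval


# ---------------------------------------------------------------------------
# bedGraph score tracks
# ---------------------------------------------------------------------------

def read_score_track(path: str | Path, manifest: GenomeManifest) -> ConservationTrack:
    """Read a 4-column bedGraph into a dense per-base track.

    Each interval ``[s, e)`` with value ``v`` fills positions ``s..e-1``.
    Uncovered positions stay NaN (missing). Overlapping intervals are an
    error because the per-base value would be ambiguous.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if df["value"].isna().any():
        raise BedFormatError(f"{path}: non-numeric or missing bedGraph value")
    track = ConservationTrack.empty(manifest)
    lengths = manifest.lengths
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise BedFormatError(f"{path}: unknown chromosome {chrom}")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        values = sub["value"].to_numpy(dtype=float)
        if (starts < 0).any() or (ends > lengths[chrom]).any():
            raise BedFormatError(
                f"{path}: interval beyond chromosome {chrom} length {lengths[chrom]}"
            )
        if (ends <= starts).any():
            raise BedFormatError(f"{path}: empty bedGraph interval on {chrom}")
        idx = np.argsort(starts, kind="stable")
        starts, ends, values = starts[idx], ends[idx], values[idx]
        if (starts[1:] < ends[:-1]).any():
            raise BedFormatError(
                f"{path}: overlapping bedGraph intervals on {chrom} (ambiguous value)"
            )
        seg_lengths = ends - starts
        total = int(seg_lengths.sum())
        offsets = np.repeat(np.cumsum(seg_lengths) - seg_lengths, seg_lengths)
        pos = np.repeat(starts, seg_lengths) + (np.arange(total) - offsets)
        track.scores[chrom][pos] = np.repeat(values, seg_lengths)
    return track


def write_score_track(
    track: ConservationTrack, path: str | Path, *, decimals: int = 4
) -> None:
    """Write the non-missing positions of a track as per-base bedGraph rows."""
    with open(path, "w") as fh:
        for name, _ in track.manifest.chroms:
            arr = track.scores[name]
            idx = np.flatnonzero(~np.isnan(arr))
            if idx.size == 0:
                continue
            vals = np.round(arr[idx], decimals)
            df = pd.DataFrame(
                {"chrom": name, "start": idx, "end": idx + 1, "value": vals}
            )
            df.to_csv(
                fh, sep="\t", header=False, index=False, float_format=f"%.{decimals}f"
            )


# ---------------------------------------------------------------------------
# Interval-set algebra (sorted, disjoint interval lists per chromosome)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    intervals = list(intervals)
    if not intervals:
        return []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval sets (each merged first)."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    for chrom in sorted({iv.chrom for iv in a} & {iv.chrom for iv in b}):
        xs = [iv for iv in a if iv.chrom == chrom]
        ys = [iv for iv in b if iv.chrom == chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i].start, ys[j].start)
            e = min(xs[i].end, ys[j].end)
            if s < e:
                out.append(GenomicInterval(chrom, s, e))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b (each merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a:
        cuts = by_chrom_b.get(iv.chrom, [])
        pos = iv.start
        for c in cuts:
            if c.end <= pos or c.start >= iv.end:
                continue
            if c.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, c.start))
            pos = max(pos, c.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by an interval set (overlaps counted once)."""
    return sum(iv.length() for iv in merge_intervals(intervals))
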