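"""Synthetic toy datasets with planted "truncated enhancer" structure.

The generator emulates, at desk scale, the data shapes the analysis
consumes: a small genome with peak-covered regions, non-overlapping
predicted CRM candidates (CRMCs) inside those regions, validated elements
(VPR/VNR) planted as truncations of host CRMCs plus short neutral
extensions, a per-base conservation track with a shifted score
distribution over CRMC bases, a per-CRMC per-tissue activation table with
lineage-correlated tissues, and a deterministic variant scorer whose
impact follows the conservation track.

Every quantity the downstream statistics estimate (truncation fraction,
extension fraction, conservation shift, host p-values, tissue blocks,
impact gain) is a generator parameter recorded in :class:`GroundTruth`,
so each pipeline stage has a parameter-recovery oracle.

The VPR/VNR labels are assigned by an independent Bernoulli draw — the
two classes are exchangeable *by construction*, which is exactly the null
under which class-contrast statistics should find no difference.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    ConservationTrack,
    Crmc,
    GenomeManifest,
    GenomicInterval,
    ValidatedElement,
    write_bed,
    write_score_track,
)

# ground-truth per-base classes
NON_CRMC = 0
CRMC_CORE = 1
ELEMENT_EXTENSION = 2


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from a single global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass
class SyntheticConfig:
    """Parameters of the planted structure.

    Defaults are the study conditions of the full synthetic experiment:
    500 CRMCs of mean length 2 kb in half-covered 6 Mb toy genome, with
    60% of CRMCs hosting one validated element truncated to on average
    half the host length (f = 0.5) and extended so that on average 10% of
    element bases fall outside the host in neutral sequence (x = 0.10).
    CRMC bases score N(1.5, 1) on the conservation track against N(0, 1)
    for everything else.
    """

    seed: int = 0
    # genome layout
    n_chroms: int = 4
    chrom_length_bp: int = 1_500_000
    coverage_fraction: float = 0.5
    n_covered_per_chrom: int = 8
    # CRMCs
    n_crmcs: int = 500
    crmc_length_mean: float = 2000.0
    crmc_length_sd: float = 400.0
    min_crmc_length: int = 200
    min_gap: int = 400
    # planted elements
    element_fraction: float = 0.6
    truncation_fraction: float = 0.5  # f: E[element length / host length]
    truncation_sd: float = 0.05
    extension_fraction: float = 0.10  # x: E[element bases outside host]
    vpr_fraction: float = 0.5
    # conservation scores
    conserved_mean: float = 1.5
    conserved_sd: float = 1.0
    neutral_sd: float = 1.0
    # prediction p-values (log-uniform components)
    host_p_range: tuple[float, float] = (1e-8, 1e-6)
    decoy_p_range: tuple[float, float] = (1e-4, 1.0)
    # tissue activation
    n_tissues: int = 12
    n_lineage_blocks: int = 3
    block_active_prob: float = 0.4
    active_prob_mean: float = 0.85
    inactive_prob_mean: float = 0.10
    prob_noise_sd: float = 0.05
    # synthetic variant scorer
    impact_gain: float = 0.5
    impact_noise_sd: float = 0.05
    n_impact_features: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.truncation_fraction <= 1.0):
            raise ValueError("truncation_fraction must be in (0, 1]")
        if not (0.0 <= self.extension_fraction < 1.0):
            raise ValueError("extension_fraction must be in [0, 1)")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not (0.0 <= self.element_fraction <= 1.0):
            raise ValueError("element_fraction must be in [0, 1]")
        for name in ("crmc_length_sd", "truncation_sd", "conserved_sd",
                     "neutral_sd", "prob_noise_sd", "impact_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Per-base class labels and per-element planting bookkeeping."""

    base_classes: dict[str, np.ndarray]  # int8 arrays per chromosome
    hosts: dict[str, str]  # element id -> host CRMC id
    element_shared_bp: dict[str, int]
    element_extension_bp: dict[str, int]

    def class_sizes(self) -> dict[str, int]:
        sizes = {"non_crmc": 0, "crmc_core": 0, "element_extension": 0}
        for arr in self.base_classes.values():
            sizes["non_crmc"] += int((arr == NON_CRMC).sum())
            sizes["crmc_core"] += int((arr == CRMC_CORE).sum())
            sizes["element_extension"] += int((arr == ELEMENT_EXTENSION).sum())
        return sizes

    def summary(self) -> dict:
        return {
            "class_sizes": self.class_sizes(),
            "hosts": self.hosts,
            "element_shared_bp": self.element_shared_bp,
            "element_extension_bp": self.element_extension_bp,
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    manifest: GenomeManifest
    covered: list[GenomicInterval]
    crmcs: list[Crmc]
    elements: list[ValidatedElement]
    track: ConservationTrack
    crmc_states: pd.DataFrame  # index CRMC ids, columns tissue names
    truth: GroundTruth
    _sequences: dict[str, str] | None = field(default=None, repr=False)

    def sequences(self) -> dict[str, str]:
        """Random ACGT reference sequence per chromosome (lazily generated)."""
        if self._sequences is None:
            rng = substream(self.config.seed, "sequence")
            letters = np.frombuffer(b"ACGT", dtype="S1")
            self._sequences = {
                name: letters[rng.integers(0, 4, size=length)].tobytes().decode()
                for name, length in self.manifest.chroms
            }
        return self._sequences

    def write(self, outdir: str | Path, *, fasta: bool = True) -> None:
        """Write the dataset as the plain-text files downstream stages read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest.to_chrom_sizes(outdir / "chrom.sizes")
        write_bed(self.covered, outdir / "covered.bed", manifest=self.manifest, sort=True)
        write_bed(self.crmcs, outdir / "crmcs.bed", manifest=self.manifest, sort=True)
        write_bed(self.elements, outdir / "elements.bed", manifest=self.manifest, sort=True)
        write_score_track(self.track, outdir / "conservation.bedGraph")
        self.crmc_states.to_csv(
            outdir / "crmc_states.tsv", sep="\t", index_label="crmc_id",
            float_format="%.6f",
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth.summary(), fh, indent=2, sort_keys=True)
        if fasta:
            with open(outdir / "genome.fa", "w") as fh:
                for name, _ in self.manifest.chroms:
                    fh.write(f">{name}\n")
                    seq = self.sequences()[name]
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")


def _covered_segments(cfg: SyntheticConfig) -> tuple[GenomeManifest, list[GenomicInterval]]:
    manifest = GenomeManifest(
        [(f"chr{i + 1}", cfg.chrom_length_bp) for i in range(cfg.n_chroms)]
    )
    covered = []
    n_seg = cfg.n_covered_per_chrom
    spacing = cfg.chrom_length_bp // n_seg
    seg_len = int(round(spacing * cfg.coverage_fraction))
    pad = (spacing - seg_len) // 2
    for name, _ in manifest.chroms:
        for i in range(n_seg):
            start = i * spacing + pad
            covered.append(GenomicInterval(name, start, start + seg_len))
    return manifest, covered


def _place_crmcs(
    cfg: SyntheticConfig, covered: list[GenomicInterval], rng: np.random.Generator
) -> list[Crmc]:
    lengths = np.maximum(
        cfg.min_crmc_length,
        np.round(rng.normal(cfg.crmc_length_mean, cfg.crmc_length_sd, cfg.n_crmcs)),
    ).astype(int)
    # round-robin assignment of CRMCs to covered segments
    seg_members: list[list[int]] = [[] for _ in covered]
    for i in range(cfg.n_crmcs):
        seg_members[i % len(covered)].append(i)
    placements: dict[int, GenomicInterval] = {}
    for seg, members in zip(covered, seg_members):
        if not members:
            continue
        mass = int(lengths[members].sum())
        free = seg.length() - mass - (len(members) + 1) * cfg.min_gap
        if free < 0:
            raise ValueError(
                f"requested CRMC mass ({mass} bp + gaps) exceeds covered segment "
                f"{seg.chrom}:{seg.start}-{seg.end} capacity ({seg.length()} bp)"
            )
        extra = rng.multinomial(free, np.full(len(members) + 1, 1.0 / (len(members) + 1)))
        pos = seg.start
        for k, idx in enumerate(members):
            pos += cfg.min_gap + int(extra[k])
            placements[idx] = GenomicInterval(seg.chrom, pos, pos + int(lengths[idx]))
            pos += int(lengths[idx])
    order = sorted(placements, key=lambda i: (placements[i].chrom, placements[i].start))
    return [
        Crmc(placements[i], f"C{rank:05d}", 1.0)  # p-values assigned later
        for rank, i in enumerate(order)
    ]


def _plant_elements(
    cfg: SyntheticConfig,
    manifest: GenomeManifest,
    crmcs: list[Crmc],
    rng: np.random.Generator,
) -> tuple[list[ValidatedElement], dict[str, str], dict[str, int], dict[str, int]]:
    n_hosts = int(round(cfg.element_fraction * len(crmcs)))
    host_idx = np.sort(rng.choice(len(crmcs), size=n_hosts, replace=False))
    # neighbour CRMC boundaries limit how far extensions may reach
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(crmcs):
        by_chrom.setdefault(c.interval.chrom, []).append(i)
    prev_end: dict[int, int] = {}
    next_start: dict[int, int] = {}
    lengths = manifest.lengths
    for chrom, idxs in by_chrom.items():
        for k, i in enumerate(idxs):
            prev_end[i] = crmcs[idxs[k - 1]].interval.end if k > 0 else 0
            next_start[i] = (
                crmcs[idxs[k + 1]].interval.start if k + 1 < len(idxs) else lengths[chrom]
            )
    elements, hosts, shared_bp, ext_bp = [], {}, {}, {}
    for n, i in enumerate(host_idx):
        host = crmcs[int(i)]
        s, e = host.interval.start, host.interval.end
        L = e - s
        f_i = float(np.clip(rng.normal(cfg.truncation_fraction, cfg.truncation_sd), 0.05, 1.0))
        Le = max(1, min(L, int(round(f_i * L))))
        ne = int(rng.binomial(Le, cfg.extension_fraction)) if cfg.extension_fraction > 0 else 0
        side = int(rng.integers(0, 2))  # 0 = left, 1 = right
        # extensions may not reach the neighbouring CRMC (half the gap each way)
        gap_room = (
            (s - prev_end[int(i)]) // 2 if side == 0 else (next_start[int(i)] - e) // 2
        )
        ne = min(ne, max(0, gap_room), Le - 1) if ne > 0 else 0
        inside = Le - ne
        if ne == 0:
            start_el = s + int(rng.integers(0, L - Le + 1))
            iv = GenomicInterval(host.interval.chrom, start_el, start_el + Le)
        elif side == 1:
            iv = GenomicInterval(host.interval.chrom, e - inside, e + ne)
        else:
            iv = GenomicInterval(host.interval.chrom, s - ne, s + inside)
        el_id = f"E{n:04d}"
        elements.append(ValidatedElement(iv, el_id, "VPR"))  # labels assigned later
        hosts[el_id] = host.id
        shared_bp[el_id] = inside
        ext_bp[el_id] = ne
    return elements, hosts, shared_bp, ext_bp


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete toy dataset from a single seed.

    All randomness flows through named substreams of ``config.seed``, so
    two calls with equal configs produce identical datasets, and changing
    one component's parameters (e.g. scorer noise) leaves the others'
    draws untouched.
    """
    cfg = config
    manifest, covered = _covered_segments(cfg)
    if cfg.n_crmcs > 0:
        crmcs = _place_crmcs(cfg, covered, substream(cfg.seed, "placement"))
        elements, hosts, shared_bp, ext_bp = _plant_elements(
            cfg, manifest, crmcs, substream(cfg.seed, "elements")
        )
    else:
        crmcs, elements, hosts, shared_bp, ext_bp = [], [], {}, {}, {}

    # labels: Bernoulli, independent of all structure (exchangeable classes)
    rng_lab = substream(cfg.seed, "labels")
    labels = ["VPR" if rng_lab.random() < cfg.vpr_fraction else "VNR" for _ in elements]
    elements = [
        ValidatedElement(el.interval, el.id, lab) for el, lab in zip(elements, labels)
    ]

    # p-values: hosts from the small-p component, decoys from the broad one
    rng_p = substream(cfg.seed, "pvalues")
    host_ids = set(hosts.values())

    def _logu(rng, lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    crmcs = [
        Crmc(
            c.interval,
            c.id,
            _logu(rng_p, *(cfg.host_p_range if c.id in host_ids else cfg.decoy_p_range)),
        )
        for c in crmcs
    ]

    # ground-truth base classes
    base = {name: np.zeros(length, dtype=np.int8) for name, length in manifest.chroms}
    for c in crmcs:
        base[c.interval.chrom][c.interval.start : c.interval.end] = CRMC_CORE
    for el in elements:
        arr = base[el.interval.chrom]
        sl = arr[el.interval.start : el.interval.end]
        sl[sl == NON_CRMC] = ELEMENT_EXTENSION
    truth = GroundTruth(base, hosts, shared_bp, ext_bp)

    # conservation track: neutral background, shifted scores over CRMC bases
    rng_sc = substream(cfg.seed, "scores")
    scores = {}
    for name, length in manifest.chroms:
        scores[name] = rng_sc.normal(0.0, cfg.neutral_sd, size=length)
    for c in crmcs:
        scores[c.interval.chrom][c.interval.start : c.interval.end] = rng_sc.normal(
            cfg.conserved_mean, cfg.conserved_sd, size=c.interval.length()
        )
    track = ConservationTrack(scores, manifest)

    # per-CRMC tissue activation with lineage-correlated blocks
    rng_st = substream(cfg.seed, "states")
    tissues = [f"tissue{j:02d}" for j in range(cfg.n_tissues)]
    block_of = np.array(
        [j * cfg.n_lineage_blocks // cfg.n_tissues for j in range(cfg.n_tissues)]
    )
    n = len(crmcs)
    active_block = rng_st.random((n, cfg.n_lineage_blocks)) < cfg.block_active_prob
    means = np.where(
        active_block[:, block_of], cfg.active_prob_mean, cfg.inactive_prob_mean
    )
    probs = np.clip(
        means + rng_st.normal(0.0, cfg.prob_noise_sd, size=(n, cfg.n_tissues)), 0.0, 1.0
    )
    crmc_states = pd.DataFrame(probs, index=[c.id for c in crmcs], columns=tissues)

    return SyntheticDataset(
        cfg, manifest, covered, crmcs, elements, track, crmc_states, truth
    )


class SyntheticVariantScorer:
    """Deterministic stand-in for an external variant-effect model.

    The aggregated absolute impact of mutating the base at window offset
    ``o`` follows ``|gain * |phyloP(pos)| * w(o) + noise|`` with ``w`` a
    triangular kernel peaking at the window midpoint, so impact profiles
    track the conservation track by construction. Per-call feature
    vectors carry random signs so that both mean- and max-of-absolute
    feature aggregation recover the modelled magnitude.

    Scores are deterministic given (seed, window id, position, allele):
    the full window tensor is drawn from a per-window substream and
    cached, and single calls index into it.
    """

    def __init__(
        self,
        track: ConservationTrack,
        *,
        gain: float = 0.5,
        noise_sd: float = 0.05,
        n_features: int = 4,
        seed: int = 0,
    ):
        self.track = track
        self.gain = gain
        self.noise_sd = noise_sd
        self.n_features = n_features
        self.seed = int(seed) & 0x7FFFFFFF
        self._cache: dict[str, np.ndarray] = {}

    @staticmethod
    def kernel(window_size: int) -> np.ndarray:
        half = window_size // 2
        offsets = np.arange(window_size) - half
        return 1.0 - np.abs(offsets) / half

    def score_window(self, window) -> np.ndarray:
        """Full (window_size, 3 alleles, n_features) score tensor, cached."""
        key = window.element_id
        if key in self._cache:
            return self._cache[key]
        W = window.interval.length()
        cons = np.abs(self.track.slice(window.interval))
        target = self.gain * cons * self.kernel(W)  # (W,)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [self.seed, zlib.crc32(b"scorer"), zlib.crc32(key.encode())]
            )
        )
        eps = rng.normal(0.0, self.noise_sd, size=(W, 3)) if self.noise_sd > 0 else np.zeros((W, 3))
        signs = rng.choice([-1.0, 1.0], size=(W, 3, self.n_features))
        tensor = signs * (target[:, None] + eps)[:, :, None]
        self._cache[key] = tensor
        return tensor

    def __call__(self, window, position: int, alt: str) -> np.ndarray:
        """Feature scores for mutating window offset ``position`` to ``alt``."""
        if window.sequence is None:
            raise ValueError("window has no reference sequence")
        ref = window.sequence[position].upper()
        if ref not in "ACGT":
            raise ValueError(f"ambiguous reference base {ref!r} at position {position}")
        alt = alt.upper()
        if alt == ref:
            raise ValueError(f"alt allele {alt} equals reference at position {position}")
        alts = [b for b in "ACGT" if b != ref]
        if alt not in alts:
            raise ValueError(f"invalid alt allele {alt!r}")
        return self.score_window(window)[position, alts.index(alt)].copy()
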