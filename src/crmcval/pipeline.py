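"""End-to-end orchestration: generate -> recall -> partition -> states -> mutprofile.

One YAML-serialisable config drives all stages from a single seed. Every
stage reads its inputs from the files the previous stage wrote, so any
stage can be re-run in isolation against an existing output directory,
and the final ``report.json`` collects the headline statistics of each
stage. Reports are written with sorted keys so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import activation, mutagenesis, partition as partition_mod, recall as recall_mod
from .genomic_io import GenomeManifest, read_bed, read_score_track
from .synthetic import SyntheticConfig, SyntheticVariantScorer, generate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    outdir: Path = Path("crmcval_run")
    cutoffs: tuple[float, ...] = (1e-6, 5e-5, 1e-3, 0.05)
    recall_cutoff: float = 5e-5
    min_overlap_bp: int = 1
    reciprocal_threshold: float = 0.5
    combine: str = "max"
    t_active: float = 0.5
    window_size: int = 2000
    feature_agg: str = "mean"
    neutral_threshold: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["outdir"] = str(self.outdir)
        data["cutoffs"] = list(self.cutoffs)
        data["synthetic"]["host_p_range"] = list(self.synthetic.host_p_range)
        data["synthetic"]["decoy_p_range"] = list(self.synthetic.decoy_p_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        syn = data.pop("synthetic", {})
        for key in ("host_p_range", "decoy_p_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        data["synthetic"] = SyntheticConfig(**syn)
        data["outdir"] = Path(data.get("outdir", "crmcval_run"))
        data["cutoffs"] = tuple(data.get("cutoffs", (1e-6, 5e-5, 1e-3, 0.05)))
        return cls(**data)


#: named parameter profiles: the toy profile is a fast smoke-scale run;
#: human/mouse carry the species presets (recall cutoff 5e-5, cutoff grid
#: ending at 0.05, 50% reciprocal transfer, 2 kb windows, neutral
#: thresholds 1.0 / 0.7) at the full synthetic study scale.
def profile_config(name: str, outdir: str | Path, seed: int = 0) -> RunConfig:
    if name == "toy":
        syn = SyntheticConfig(
            seed=seed, n_chroms=2, chrom_length_bp=150_000, n_covered_per_chrom=4,
            n_crmcs=60, crmc_length_mean=1000.0, crmc_length_sd=200.0,
            n_tissues=8, n_lineage_blocks=2,
        )
        return RunConfig(synthetic=syn, outdir=Path(outdir))
    if name in ("human", "mouse"):
        syn = SyntheticConfig(seed=seed)
        return RunConfig(
            synthetic=syn, outdir=Path(outdir),
            neutral_threshold=mutagenesis.NEUTRAL_THRESHOLDS[name],
        )
    raise ValueError(f"unknown profile {name!r}; expected toy, human or mouse")


# ---------------------------------------------------------------------------
# stages (each reads its inputs from disk, writes its outputs to disk)
# ---------------------------------------------------------------------------

def stage_generate(config: RunConfig) -> Path:
    gen_dir = Path(config.outdir) / "generate"
    dataset = generate_dataset(config.synthetic)
    dataset.write(gen_dir)
    return gen_dir


def _load_inputs(config: RunConfig):
    gen_dir = Path(config.outdir) / "generate"
    manifest = GenomeManifest.from_chrom_sizes(gen_dir / "chrom.sizes")
    covered = read_bed(gen_dir / "covered.bed", kind="plain")
    crmcs = read_bed(gen_dir / "crmcs.bed", kind="crmc")
    elements = read_bed(gen_dir / "elements.bed", kind="element")
    return gen_dir, manifest, covered, crmcs, elements


def stage_recall(config: RunConfig) -> dict:
    gen_dir, manifest, covered, crmcs, elements = _load_inputs(config)
    if not crmcs:
        raise ValueError("no CRMCs in the generated dataset; nothing to recall")
    out = Path(config.outdir) / "recall"
    out.mkdir(parents=True, exist_ok=True)
    curve = recall_mod.sensitivity_curve(
        elements, crmcs, covered, list(config.cutoffs), config.synthetic.seed,
        min_overlap_bp=config.min_overlap_bp,
    )
    rows = []
    for i, cut in enumerate(curve.cutoffs):
        chi2 = curve.chi2[i]
        rows.append({
            "cutoff": cut,
            "n_elements": curve.crmc_results[i].n_elements,
            "n_recalled_crmc": curve.crmc_results[i].n_recalled,
            "sensitivity_crmc": curve.crmc_sensitivity[i],
            "n_recalled_control": curve.control_results[i].n_recalled,
            "sensitivity_control": curve.control_sensitivity[i],
            "chi2": chi2.statistic,
            "p": chi2.p_value,
            "degenerate": chi2.degenerate,
        })
    pd.DataFrame(rows).to_csv(out / "recall_curve.tsv", sep="\t", index=False)
    res = recall_mod.recall_elements(
        elements, crmcs, config.recall_cutoff, min_overlap_bp=config.min_overlap_bp
    )
    pd.DataFrame({
        "element_id": list(res.element_ids),
        "recalling_crmc": [res.recalling[e] or "." for e in res.element_ids],
    }).to_csv(out / "recall_assignments.tsv", sep="\t", index=False)
    at_cut = [r for r in rows if r["cutoff"] == config.recall_cutoff]
    return {
        "curve": rows,
        "at_recall_cutoff": at_cut[0] if at_cut else rows[-1],
        "seed": config.synthetic.seed,
    }


def _load_recall_result(config: RunConfig, elements) -> recall_mod.RecallResult:
    path = Path(config.outdir) / "recall" / "recall_assignments.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str)
    recalling = {
        r.element_id: (None if r.recalling_crmc == "." else r.recalling_crmc)
        for r in df.itertuples(index=False)
    }
    return recall_mod.RecallResult(
        config.recall_cutoff, config.min_overlap_bp,
        tuple(df["element_id"]), recalling,
    )


def stage_partition(config: RunConfig) -> dict:
    gen_dir, manifest, covered, crmcs, elements = _load_inputs(config)
    track = read_score_track(gen_dir / "conservation.bedGraph", manifest)
    res = _load_recall_result(config, elements)
    out = Path(config.outdir) / "partition"
    out.mkdir(parents=True, exist_ok=True)
    part = partition_mod.partition_positions(res, elements, crmcs)
    samples = part.score_samples(track)
    for name, sample in samples.items():
        pd.Series(sample, name="phylop").to_csv(
            out / f"scores_{name}.tsv", sep="\t", index=False, float_format="%.4f"
        )
    ratios = partition_mod.length_ratios(res, elements, crmcs)
    pd.Series(ratios.ratios, name="ratio").to_csv(
        out / "ratios.tsv", sep="\t", index=False, float_format="%.6f"
    )
    ks_shared_el = partition_mod.compare_distributions(
        samples["shared"], samples["element_specific"]
    )
    ks_shared_cr = partition_mod.compare_distributions(
        samples["shared"], samples["crmc_specific"]
    )
    total_el = part.total_element_bp
    report = {
        "shared_bp": part.shared_bp,
        "crmc_specific_bp": part.crmc_specific_bp,
        "element_specific_bp": part.element_specific_bp,
        "shared_fraction_of_element_bp": part.shared_bp / total_el if total_el else None,
        "element_specific_fraction": part.element_specific_bp / total_el if total_el else None,
        "ks_shared_vs_element_specific": {"D": ks_shared_el[0], "p": ks_shared_el[1]},
        "ks_shared_vs_crmc_specific": {"D": ks_shared_cr[0], "p": ks_shared_cr[1]},
        "length_ratio": {
            "mean": ratios.mean, "median": ratios.median,
            "q1": ratios.quartiles[0], "q3": ratios.quartiles[1],
            "n": int(ratios.ratios.size),
        },
    }
    with open(out / "partition.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def stage_states(config: RunConfig) -> dict:
    gen_dir, manifest, covered, crmcs, elements = _load_inputs(config)
    states = pd.read_csv(gen_dir / "crmc_states.tsv", sep="\t", index_col="crmc_id")
    out = Path(config.outdir) / "states"
    out.mkdir(parents=True, exist_ok=True)
    matrix = activation.transfer_states(
        elements, crmcs, states,
        threshold=config.reciprocal_threshold,
        combine=config.combine, t_active=config.t_active,
    )
    mat_out = matrix.probs.copy()
    mat_out.insert(0, "label", matrix.labels)
    mat_out.to_csv(out / "activation_matrix.tsv", sep="\t", index_label="element_id",
                   float_format="%.6f")
    (out / "dropped_elements.txt").write_text("".join(f"{e}\n" for e in matrix.no_match))
    breadth = activation.activity_breadth(matrix)
    complete = matrix.complete()
    clustering = None
    if complete.probs.shape[0] >= 2 and complete.probs.shape[1] >= 2:
        clustering = activation.cluster_two_way(complete)
        with open(out / "leaf_orders.json", "w") as fh:
            json.dump(
                {"rows": clustering.row_order, "cols": clustering.col_order},
                fh, indent=2,
            )
    report = {
        "n_elements_with_states": {k: int(v) for k, v in breadth.n_elements.items()},
        "n_dropped": len(matrix.no_match),
        "fraction_active_in_ge1_tissue": breadth.fraction_active,
        "k_histogram": {
            cls: {str(k): v for k, v in hist.items()}
            for cls, hist in breadth.k_histogram.items()
        },
        "per_tissue_active_counts": {
            cls: {t: int(c) for t, c in breadth.per_tissue_counts[cls].items()}
            for cls in breadth.per_tissue_counts.columns
        },
        "clustered": clustering is not None,
    }
    with open(out / "breadth.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def stage_mutprofile(config: RunConfig) -> dict:
    gen_dir, manifest, covered, crmcs, elements = _load_inputs(config)
    track = read_score_track(gen_dir / "conservation.bedGraph", manifest)
    sequences = Fasta(str(gen_dir / "genome.fa"))
    out = Path(config.outdir) / "mutprofile"
    out.mkdir(parents=True, exist_ok=True)
    scorer = SyntheticVariantScorer(
        track,
        gain=config.synthetic.impact_gain,
        noise_sd=config.synthetic.impact_noise_sd,
        n_features=config.synthetic.n_impact_features,
        seed=config.synthetic.seed,
    )
    report = {}
    for cls in ("VPR", "VNR"):
        cls_elements = [el for el in elements if el.label == cls]
        windows = mutagenesis.extract_windows(
            cls_elements, manifest, window_size=config.window_size, sequences=sequences
        )
        if not windows:
            report[cls] = {"n_windows": 0, "r": None, "n_offsets_retained": None,
                           "peak_offset": None}
            continue
        imp = mutagenesis.average_profile(windows, scorer, config.feature_agg)
        cons = mutagenesis.conservation_profile(windows, track)
        pd.DataFrame({
            "offset": imp.offsets, "mean_impact": imp.mean_impact, "n": imp.counts,
            "mean_abs_cons": cons.mean_abs_score, "n_cons": cons.counts,
        }).to_csv(out / f"profile_{cls}.tsv", sep="\t", index=False,
                  float_format="%.6f")
        r, n_kept = mutagenesis.impact_conservation_correlation(
            imp, cons, config.neutral_threshold
        )
        peak = int(imp.offsets[int(np.nanargmax(imp.mean_impact))])
        report[cls] = {
            "n_windows": len(windows), "r": r, "n_offsets_retained": n_kept,
            "peak_offset": peak,
        }
    with open(out / "correlation.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _generate_chunk(cfg: RunConfig) -> dict:
    stage_generate(cfg)
    return {
        "outdir": "generate",  # relative to the run directory
        "n_crmcs": cfg.synthetic.n_crmcs,
        "seed": cfg.synthetic.seed,
    }


STAGES = (
    ("generate", _generate_chunk),
    ("recall", stage_recall),
    ("partition", stage_partition),
    ("states", stage_states),
    ("mutprofile", stage_mutprofile),
)


def run_all(config: RunConfig) -> dict:
    """Run every stage in order and write ``report.json``.

    A stage failure aborts the run with the stage name and cause; outputs
    of completed stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"seeds": {"global": config.synthetic.seed}}
    for name, fn in STAGES:
        logger.info("running stage %s", name)
        try:
            report[name] = fn(config)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "type": "object",
    "required": ["seeds", "generate", "recall", "partition", "states", "mutprofile"],
    "properties": {
        "seeds": {"type": "object", "required": ["global"]},
        "generate": {"type": "object", "required": ["outdir"]},
        "recall": {"type": "object", "required": ["curve", "at_recall_cutoff"]},
        "partition": {
            "type": "object",
            "required": [
                "shared_bp", "crmc_specific_bp", "element_specific_bp",
                "ks_shared_vs_element_specific", "length_ratio",
            ],
        },
        "states": {
            "type": "object",
            "required": [
                "n_elements_with_states", "fraction_active_in_ge1_tissue",
                "k_histogram", "per_tissue_active_counts",
            ],
        },
        "mutprofile": {"type": "object", "required": ["VPR", "VNR"]},
    },
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA, path: str = "report") -> None:
    """Minimal structural validation against the shipped report schema."""
    if schema.get("type") == "object":
        if not isinstance(report, dict):
            raise ValueError(f"{path}: expected object, got {type(report).__name__}")
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
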