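"""Independent brute-force per-base oracles used to cross-check the
interval-arithmetic implementations on small genomes.

These deliberately share no code with the package's recall/partition
logic: everything is computed on dense boolean masks over the genome.
"""

from __future__ import annotations

import numpy as np

from crmcval.genomic_io import GenomeManifest


def _masks(manifest: GenomeManifest):
    return {name: np.zeros(length, dtype=bool) for name, length in manifest.chroms}


def brute_recall(elements, crmcs, cutoff, min_overlap_bp, manifest):
    """Per-element recall flags by scanning eligible-CRMC base coverage."""
    flags = {}
    for el in elements:
        best = 0
        for c in crmcs:
            if c.p_value > cutoff or c.interval.chrom != el.interval.chrom:
                continue
            mask = np.zeros(manifest.lengths[el.interval.chrom], dtype=bool)
            mask[c.interval.start : c.interval.end] = True
            ov = int(mask[el.interval.start : el.interval.end].sum())
            best = max(best, ov)
        flags[el.id] = best >= min_overlap_bp
    return flags


def brute_partition(elements, crmcs, cutoff, min_overlap_bp, manifest):
    """(shared, crmc_specific, element_specific) bp via boolean masks."""
    flags = brute_recall(elements, crmcs, cutoff, min_overlap_bp, manifest)
    recalled = [el for el in elements if flags[el.id]]
    E = _masks(manifest)
    for el in recalled:
        E[el.interval.chrom][el.interval.start : el.interval.end] = True
    C = _masks(manifest)
    for c in crmcs:
        if c.p_value > cutoff:
            continue
        qualifies = False
        for el in recalled:
            if el.interval.chrom != c.interval.chrom:
                continue
            mask = np.zeros(manifest.lengths[c.interval.chrom], dtype=bool)
            mask[c.interval.start : c.interval.end] = True
            if int(mask[el.interval.start : el.interval.end].sum()) >= min_overlap_bp:
                qualifies = True
                break
        if qualifies:
            C[c.interval.chrom][c.interval.start : c.interval.end] = True
    shared = crmc_spec = el_spec = 0
    for name, _ in manifest.chroms:
        shared += int((E[name] & C[name]).sum())
        el_spec += int((E[name] & ~C[name]).sum())
        crmc_spec += int((C[name] & ~E[name]).sum())
    return shared, crmc_spec, el_spec
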