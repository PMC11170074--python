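# crmcval

Comparative analysis of validated enhancer regions against predicted
cis-regulatory module candidates (CRMCs), built around the hypothesis
that assay-validated regions — both validated positive regions (VPRs)
and validated negative regions (VNRs) — are *truncated forms of longer
bona fide enhancers*.

The package is for computational regulatory-genomics work: it implements
the full statistical pipeline one runs when comparing a set of validated
elements (VISTA-style BED exports) against a genome-wide CRMC prediction
map with per-element p-values, a per-base phyloP conservation track, a
per-CRMC per-tissue activation table, and a variant-effect scorer — and
it ships a synthetic-data generator that plants the truncated-enhancer
structure with known parameters, so every stage of the analysis has a
parameter-recovery test.

## What it computes

Let E be validated elements and C = {c : p(c) ≤ α} the CRMCs passing a
prediction p-value cutoff α (default α = 5×10⁻⁵).

- **Recall with a matched-control null.** e ∈ E is *recalled* when some
  c ∈ C overlaps it by ≥ 1 bp (configurable); sensitivity = recalled/|E|.
  The null re-places each CRMC as a random segment of identical length
  uniformly inside the TF-peak-covered regions; CRMC vs control recall
  is compared by a χ² test on the 2×2 table (no continuity correction).
- **Position partition.** Bases of recalled elements and their
  recalling CRMCs split into *shared* = |E ∩ C|, *element-specific* =
  |E \ C| and *CRMC-specific* = |C \ E| (each base counted once);
  per-class phyloP distributions are contrasted with two-sample K-S
  tests, and per-element length ratios len(c)/len(e) are summarised.
- **Functional-state transfer.** An element inherits per-tissue
  activation probabilities from every CRMC with ≥ 50% *reciprocal*
  overlap (overlap ≥ t·len(a) and ≥ t·len(b)); combined by max (or
  overlap-weighted mean), thresholded into binary active calls,
  two-way clustered, and summarised as "active in k tissues" breadth.
- **In-silico mutagenesis profiles.** For each element a 2000 bp window
  anchored at the midpoint; per position the impact is the max over the
  three alternative alleles of the aggregated absolute feature scores
  from a pluggable variant scorer; per-offset means are correlated with
  mean |phyloP| after removing neutral offsets (mean |phyloP| below 1.0
  or 0.7, the human/mouse presets).

## Worked example

```python
from crmcval import SyntheticConfig, generate_dataset, recall_elements
from crmcval.partition import partition_positions, compare_distributions, length_ratios

ds = generate_dataset(SyntheticConfig(seed=0))   # 500 CRMCs, 300 planted elements
res = recall_elements(ds.elements, ds.crmcs, 5e-5)
part = partition_positions(res, ds.elements, ds.crmcs)
samples = part.score_samples(ds.track)
```

Running `python examples/03_position_partition.py` (which does exactly
this) prints:

```
shared positions:            268,794 (89.9% of element bases)
element-specific positions:   30,115 (10.1% of element bases)
CRMC-specific positions:     331,345
mean phyloP, shared           : +1.501 (n=268,794)
mean phyloP, crmc_specific    : +1.499 (n=331,345)
mean phyloP, element_specific : +0.005 (n=30,115)
K-S shared vs element-specific: D=0.546, p=0
median recalling-CRMC / element length ratio: 2.02
```

Reading: ~90% of element bases coincide with recalling CRMCs and carry
the shifted (conserved) score distribution, the ~10% that extend beyond
the CRMCs are neutral, and recalling CRMCs are about twice as long as
the elements — the generator's planted truncation fraction (0.5) and
extension fraction (0.10) recovered from the data. The other
`examples/*.py` scripts cover dataset generation, the recall/control
curve, state transfer with clustering, and the mutagenesis profiles.

A thin CLI mirrors the stages (`crmcval generate | recall | partition |
states | mutprofile | run`); `crmcval run --profile toy --seed 0
--outdir out/` runs everything end to end and writes `report.json`.

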