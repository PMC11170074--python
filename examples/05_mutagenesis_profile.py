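"""In-silico mutagenesis impact profiles and conservation correlation.

Scores every possible substitution in midpoint-anchored 2 kb windows
with the synthetic variant scorer, averages per-offset impacts across
elements, and correlates the profile with mean absolute conservation
after removing neutral offsets.
"""

import numpy as np

from crmcval import SyntheticConfig, SyntheticVariantScorer, generate_dataset
from crmcval.mutagenesis import (
    average_profile,
    conservation_profile,
    extract_windows,
    impact_conservation_correlation,
)

cfg = SyntheticConfig(seed=0, n_crmcs=400, element_fraction=0.5)  # 200 elements
ds = generate_dataset(cfg)
windows = extract_windows(ds.elements, ds.manifest, sequences=ds.sequences())
scorer = SyntheticVariantScorer(ds.track, gain=0.5, noise_sd=0.05, seed=0)

imp = average_profile(windows, scorer)
cons = conservation_profile(windows, ds.track)
r, n_kept = impact_conservation_correlation(imp, cons, neutral_threshold=1.0)

peak = int(imp.offsets[np.nanargmax(imp.mean_impact)])
print(f"windows scored: {len(windows)} x {imp.window_size} bp")
print(f"impact profile peak at offset {peak:+d} bp "
      f"(value {np.nanmax(imp.mean_impact):.3f})")
print(f"impact at midpoint {imp.mean_impact[1000]:.3f}, "
      f"at offset +900 {imp.mean_impact[1900]:.3f}")
print(f"Pearson r(impact, |phyloP|) = {r:.3f} over {n_kept} non-neutral offsets")
# The profile peaks at the window midpoint and decays outward (the
# scorer's triangular kernel times local conservation); after dropping
# neutral offsets the impact profile tracks conservation almost linearly.
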