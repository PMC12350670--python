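"""Rank-abundance structure, sequence logos and validation correlations.

Shows the repertoire-level statistics: singleton / low-count fractions of the
rank-abundance distribution, a CDR3 position-frequency logo, and a Pearson
correlation of NGS prevalence against an external per-clone measurement.
"""

import numpy as np

from vnarscope import (
    AffinityRecord,
    SimulationParams,
    abundance_fractions,
    build_logo,
    collapse_unique,
    filter_full_length,
    prevalence_affinity_correlation,
    rank_abundance_series,
    simulate,
)

sim = simulate(SimulationParams(seed=3, n_reads=20_000))
result = filter_full_length(sim.reads["target"], sim.anchors)
ds = collapse_unique(result.sequences, "target")
ds.annotate()

fractions = abundance_fractions(ds, thresholds=[10])
print(f"{fractions.n_clones} unique clones; "
      f"{100 * fractions.singleton_fraction:.1f}% singletons; "
      f"{100 * fractions.below[10]:.1f}% seen fewer than 10 times")
# The heavy-tailed regime typical of a diverse immunized library.

series = rank_abundance_series(ds)
print("top of the rank-abundance curve:", series[:5])

cdr3_14 = [c.cdr3 for c in ds.annotated_clones() if len(c.cdr3) == 14][:500]
logo = build_logo(cdr3_14)
print(f"logo over {len(cdr3_14)} CDR3s: consensus {''.join(logo.idxmax(axis=1))}")
# Each logo row is a per-position amino-acid frequency distribution (sums to 1).

# Correlate prevalence with a synthetic affinity table (KD log-linear in count
# plus noise, standing in for measured values, which are always consumed,
# never computed).  Panel spans the prevalence range, as a validation set would.
rng = np.random.default_rng(0)
panel = [ds.clones[min(2**i, len(ds) - 1)] for i in range(10)]
affinities = [
    AffinityRecord(c.clone_id, 10 ** (-6 - 0.8 * np.log10(c.count) + rng.normal(0, 0.2)))
    for c in panel
]
corr = prevalence_affinity_correlation(ds, affinities, transform="log10_kd")
print(f"prevalence vs affinity: r^2 = {corr.r_squared:.3f} over n = {corr.n} clones")
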