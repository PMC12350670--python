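"""Cross-library clade discovery and clonotype retrieval.

Simulates a target-immunized library and a control library sharing a Zipf
background, pools the most prevalent 14-residue CDR3s of both, builds the
neighbor-joining tree, and extracts the clades that are private to the target
library -- the in-silico candidates.  Then retrieves and sub-clusters the
clonotype of the top candidate.
"""

from vnarscope import (
    DiscoveryParams,
    clonotype_members,
    collapse_unique,
    discovery_benchmark_params,
    filter_full_length,
    run_discovery,
    simulate,
    subcluster_clonotype,
)

sim = simulate(discovery_benchmark_params(seed=0))
datasets = {}
for library in ("target", "control"):
    result = filter_full_length(sim.reads[library], sim.anchors)
    ds = collapse_unique(result.sequences, library, filter_stats=result.stats)
    ds.annotate()
    datasets[library] = ds

params = DiscoveryParams(cdr3_length=14, top_k=500, min_clade_size=30)
discovery = run_discovery(datasets["target"], datasets["control"], params)

print(f"{len(discovery.clades)} target-private clades (>=30 members, purity 1.0):")
for clade in discovery.clades:
    rep = clade.representative
    print(f"  {clade.clade_id}: {clade.size} unique CDR3s, representative "
          f"{rep.clone_id} seen {rep.count} times, CDR3 {rep.cdr3}")
# Each clade is one side of an edge bipartition of the unrooted NJ tree whose
# leaves all come from the target library; its most prevalent member is the
# candidate to express and test.

seed_cdr3 = discovery.candidates[0].cdr3
members = clonotype_members(datasets["target"], seed_cdr3, threshold=0.85)
print(f"\nclonotype around {seed_cdr3}: {len(members)} members (>85% identity)")
nodes = subcluster_clonotype(members, threshold=0.85)
print(f"sub-clustering yields {len(nodes)} discrete nodes; most prevalent per node:")
for node in nodes[:5]:
    print(f"  size {node.size}, representative count {node.representative.count}")
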