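"""NGS-guided clonotype discovery by cross-library CDR3 clustering.

A clonotype is a family of VNARs sharing a near-identical CDR3: identical
length and >85% ungapped identity by default.  Prevalence alone is a poor
predictor of antigen binding, so discovery contrasts the target-immunized
library against a control library raised to an unrelated immunogen: the most
prevalent equal-length CDR3s of both libraries are pooled, a neighbor-joining
tree is built on p-distance (1 - fractional identity), and clades populated
exclusively by target-library sequences are extracted.  The most prevalent
member of each library-pure clade is the candidate binder to express.  On an
unrooted tree, a "clade" is one side of the leaf bipartition induced by
removing an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .repertoire import RepertoireDataset, UniqueClone


@dataclass(frozen=True)
class DiscoveryParams:
    """Knobs of the discovery procedure.

    ``identity_threshold`` (default 0.85) is applied strictly (>, not >=);
    ``top_k`` (default 2000) is the per-library prevalence cut before pooling;
    ``min_clade_size`` (default 30) is inclusive; ``purity`` is the required
    fraction of clade members private to the target library (1.0 = no control
    or shared sequence anywhere in the clade).
    """

    cdr3_length: int
    identity_threshold: float = 0.85
    top_k: int = 2000
    min_clade_size: int = 30
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_clade_size < 2:
            raise ValueError("min_clade_size must be >= 2")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.cdr3_length < 1:
            raise ValueError("cdr3_length must be >= 1")


def cdr3_identity(a: str, b: str) -> float:
    """Ungapped fractional identity of two equal-length CDR3s."""
    if len(a) != len(b) or not a:
        raise ValueError("length_mismatch")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def clonotype_members(
    ds: RepertoireDataset, seed_cdr3: str, threshold: float = 0.85
) -> list[UniqueClone]:
    """All clones whose CDR3 matches the seed's length with identity strictly above threshold.

    Sorted by count descending (lexicographic tie-break on the sequence).
    """
    if not seed_cdr3:
        raise ValueError("seed CDR3 must be non-empty")
    length = len(seed_cdr3)
    members = [
        c
        for c in ds.annotated_clones()
        if len(c.cdr3) == length and cdr3_identity(c.cdr3, seed_cdr3) > threshold
    ]
    return sorted(members, key=lambda c: (-c.count, c.aa_sequence))


@dataclass
class Cdr3Group:
    """All clones of one library sharing a CDR3, keyed by the summed count."""

    cdr3: str
    count: int
    library: str
    top_clone: UniqueClone


def top_prevalent(
    ds: RepertoireDataset, cdr3_length: int, k: int
) -> list[Cdr3Group]:
    """Top ``k`` most prevalent CDR3s of exactly ``cdr3_length`` residues.

    Clones are deduplicated by CDR3 string with counts summed; ordering is by
    summed count descending with lexicographic tie-break on the CDR3.  The most
    prevalent clone carrying each CDR3 is retained as its representative.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    groups: dict[str, Cdr3Group] = {}
    for c in ds.annotated_clones():
        if len(c.cdr3) != cdr3_length:
            continue
        g = groups.get(c.cdr3)
        if g is None:
            groups[c.cdr3] = Cdr3Group(c.cdr3, c.count, ds.library, c)
        else:
            g.count += c.count
            if (c.count, g.top_clone.aa_sequence) > (g.top_clone.count, c.aa_sequence):
                # higher count wins; on equal counts the lexicographically
                # smaller sequence wins
                g.top_clone = c
    ordered = sorted(groups.values(), key=lambda g: (-g.count, g.cdr3))
    return ordered[:k]


@dataclass
class PooledLeaf:
    """One tree leaf: a CDR3 with per-library counts and representatives."""

    cdr3: str
    counts: dict[str, int] = field(default_factory=dict)
    top_clones: dict[str, UniqueClone] = field(default_factory=dict)

    @property
    def libraries(self) -> frozenset:
        return frozenset(self.counts)


@dataclass
class Cdr3Tree:
    """Neighbor-joining tree over pooled unique CDR3s (leaf names are the CDR3s)."""

    tree: TreeNode
    leaves: dict[str, PooledLeaf]

    def newick(self, annotated: bool = True) -> str:
        """Newick string; annotated leaves read ``<library>|<clone_id>|<count>``
        (multiple libraries joined with ``+``)."""
        tree = self.tree.copy()
        if annotated:
            for tip in tree.tips():
                leaf = self.leaves[tip.name]
                tip.name = "+".join(
                    f"{lib}|{leaf.top_clones[lib].clone_id}|{leaf.counts[lib]}"
                    for lib in sorted(leaf.counts)
                )
        return str(tree)


def _p_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise p-distance (1 - fractional identity) of equal-length sequences."""
    arr = np.array([list(s.encode("ascii")) for s in seqs], dtype=np.uint8)
    n = arr.shape[0]
    out = np.empty((n, n))
    block = max(1, 2**24 // max(arr.size, 1))  # bound peak memory of broadcast
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = 1.0 - (arr[start:stop, None, :] == arr[None, :, :]).mean(
            axis=2
        )
    np.fill_diagonal(out, 0.0)
    return out


def build_cdr3_tree(pool: Iterable[Cdr3Group]) -> Cdr3Tree:
    """Neighbor-joining tree on p-distance over a two-library CDR3 pool.

    CDR3s occurring in both libraries collapse to a single leaf carrying both
    labels.  Requires >= 3 pooled unique CDR3s of one common length.
    """
    leaves: dict[str, PooledLeaf] = {}
    for g in pool:
        leaf = leaves.setdefault(g.cdr3, PooledLeaf(g.cdr3))
        leaf.counts[g.library] = leaf.counts.get(g.library, 0) + g.count
        leaf.top_clones[g.library] = g.top_clone
    if len(leaves) < 3:
        raise ValueError("need at least 3 pooled CDR3s")
    names = sorted(leaves)
    lengths = {len(s) for s in names}
    if len(lengths) != 1:
        raise ValueError("length_mismatch")
    dm = DistanceMatrix(_p_distance_matrix(names), ids=names)
    tree = nj(dm)
    return Cdr3Tree(tree=tree, leaves=leaves)


@dataclass
class CladeResult:
    """A library-pure clade of the pooled CDR3 tree."""

    clade_id: str
    members: list[UniqueClone]
    cdr3s: list[str]
    source_purity: float
    representative: UniqueClone

    @property
    def size(self) -> int:
        return len(self.cdr3s)


def _bipartition_sides(tree: TreeNode) -> set[frozenset]:
    """All leaf-set sides induced by removing one edge of the (unrooted) tree."""
    all_names = frozenset(t.name for t in tree.tips())
    sides: set[frozenset] = set()
    for node in tree.postorder(include_self=False):
        below = frozenset(t.name for t in node.tips(include_self=True))
        if 0 < len(below) < len(all_names):
            sides.add(below)
            sides.add(all_names - below)
    return sides


def find_library_specific_clades(
    cdr3_tree: Cdr3Tree, target_library: str, params: DiscoveryParams
) -> list[CladeResult]:
    """Maximal clades of size >= min_clade_size whose members are target-private.

    Every edge of the unrooted tree induces a leaf bipartition; both sides are
    candidates.  A side qualifies when its fraction of target-only leaves
    (leaves never seen in any other library) is >= ``params.purity`` and its
    size is >= ``params.min_clade_size``.  Qualifying sides contained in a
    larger qualifying side are dropped (maximality).  Each clade reports the
    most prevalent target-library member as its representative; output is
    ordered by size, then representative count, descending.
    """
    leaves = cdr3_tree.leaves
    selected = []
    for side in _bipartition_sides(cdr3_tree.tree):
        if len(side) < params.min_clade_size:
            continue
        target_only = sum(
            1 for name in side if leaves[name].libraries == {target_library}
        )
        purity = target_only / len(side)
        if purity >= params.purity:
            selected.append((side, purity))

    # maximality: drop sides strictly contained in another selected side
    selected.sort(key=lambda sp: -len(sp[0]))
    maximal: list[tuple[frozenset, float]] = []
    for side, purity in selected:
        if not any(side < kept for kept, _ in maximal):
            maximal.append((side, purity))

    results = []
    for side, purity in maximal:
        members = [
            leaves[name].top_clones[target_library]
            for name in side
            if target_library in leaves[name].counts
        ]
        members.sort(key=lambda c: (-c.count, c.aa_sequence))
        representative = members[0]
        results.append(
            CladeResult(
                clade_id="",
                members=members,
                cdr3s=sorted(side),
                source_purity=purity,
                representative=representative,
            )
        )
    results.sort(
        key=lambda r: (-r.size, -r.representative.count, r.representative.aa_sequence)
    )
    for i, r in enumerate(results, start=1):
        r.clade_id = f"clade_{i}"
    return results


@dataclass
class ClonotypeNode:
    """One discrete node (single-linkage cluster) within a clonotype."""

    members: list[UniqueClone]
    representative: UniqueClone

    @property
    def size(self) -> int:
        return len(self.members)


def subcluster_clonotype(
    members: Sequence[UniqueClone], threshold: float = 0.85
) -> list[ClonotypeNode]:
    """Split clonotype members into discrete nodes by single-linkage clustering.

    Two members link when their (equal-length) CDR3 identity is strictly above
    ``threshold``; nodes are the connected components.  Each node reports its
    most prevalent clone; nodes are ordered by size then representative count.
    """
    members = list(members)
    if not members:
        return []
    lengths = {len(c.cdr3) for c in members}
    if len(lengths) != 1:
        raise ValueError("length_mismatch")

    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if cdr3_identity(members[i].cdr3, members[j].cdr3) > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    clusters: dict[int, list[UniqueClone]] = {}
    for i, c in enumerate(members):
        clusters.setdefault(find(i), []).append(c)
    nodes = []
    for group in clusters.values():
        group.sort(key=lambda c: (-c.count, c.aa_sequence))
        nodes.append(ClonotypeNode(members=group, representative=group[0]))
    nodes.sort(
        key=lambda nd: (-nd.size, -nd.representative.count, nd.representative.aa_sequence)
    )
    return nodes


@dataclass
class DiscoveryResult:
    """Ranked candidates plus the clades and tree they came from."""

    candidates: list[UniqueClone]
    clades: list[CladeResult]
    tree: Cdr3Tree

    def newick(self) -> str:
        return self.tree.newick()


def run_discovery(
    target: RepertoireDataset,
    control: RepertoireDataset,
    params: DiscoveryParams,
) -> DiscoveryResult:
    """End-to-end discovery: pool top CDR3s, build the tree, extract pure clades.

    Deterministic given the inputs and parameters.  Candidates are the clade
    representatives in clade order (largest clade first).
    """
    if target.library == control.library:
        raise ValueError("target and control libraries must have distinct labels")
    pool = top_prevalent(target, params.cdr3_length, params.top_k) + top_prevalent(
        control, params.cdr3_length, params.top_k
    )
    tree = build_cdr3_tree(pool)
    clades = find_library_specific_clades(tree, target.library, params)
    candidates = [c.representative for c in clades]
    return DiscoveryResult(candidates=candidates, clades=clades, tree=tree)
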