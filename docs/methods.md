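# Methods

## Scope and data model

`vnarscope` analyses deep sequencing of VNAR phage-display libraries starting
from *merged* amplicon reads (adapter trimming and paired-end merging are
upstream, out of scope). The central objects are the `UniqueClone` (a
deduplicated amino-acid VNAR with prevalence count and rank), the
`RepertoireDataset` (all unique clones of one library plus the filter counters
they came from), and the `CladeResult` (a library-pure clade of equal-length
CDR3s with its most prevalent representative). Coordinates are 0-based
half-open everywhere.

## Read filtering

The library construct leaves every VNAR insert flanked by conserved
nucleotide stretches. A read passes when

1. both flanks are found (leftmost match, Hamming distance ≤ a configurable
   mismatch budget, default 0; `N` always counts as a mismatch; the reverse
   complement is searched when the forward strand fails),
2. the bases strictly between the flank matches have length ≡ 0 (mod 3), and
3. translation in that frame (standard genetic code) contains no stop codon
   and no ambiguous codon.

Counters (`total ≥ anchored ≥ in_frame ≥ stop_free_full_length`) and per-read
rejection reasons (`anchor`, `frame`, `stop`, `ambiguous`) are reported. Only
one conserved flank is intrinsic to the construct design and shipped as a
default; the downstream flank is construct-specific and must be configured
(the simulator supplies its own SfiI-style cassette boundary). An empty
insert (adjacent flanks) is treated as an anchoring failure.

## Region delimitation and subtyping

No universal residue-numbering table exists for VNARs, so regions are
delimited by rules anchored on sequence landmarks, all exposed in
`NumberingScheme` and shared verbatim with the simulator:

* canonical Cys1 = first cysteine in an FR1 window (default indices 15–28);
* canonical Cys2 = first cysteine in a window at the end of FR3 (70–90);
* CDR1 spans fixed offsets after Cys1 (default +1 to +9);
* the HV4/FR3 block is a fixed length ending at Cys2 (default 28);
* CDR3 runs from Cys2+1 to the first occurrence of the conserved
  tryptophan-containing FR4 motif (default `WGQGT`);
* FR2 (containing HV2) is everything between CDR1 and HV4.

Sequences outside 80–200 aa, or missing a canonical cysteine or the FR4 motif,
are rejected with a machine-readable reason; in datasets they are retained as
*unannotated* and excluded from subtype/CDR3 statistics rather than silently
dropped.

Subtype classification uses only the placement of non-canonical cysteines
(every C except the two canonical positions), with precedence
IV → I → III → II → other:

* **IV** — no non-canonical cysteines;
* **I** — ≥1 in FR2/HV2 and ≥1 in FR4 and an even count ≥2 in CDR3 (the
  paired CDR3–framework disulfides that clamp CDR3 against HV2);
* **III** — exactly 1 in CDR1 and ≥1 in CDR3 with a tryptophan adjacent to
  the CDR1 cysteine (the conserved CDR1 context that distinguishes the
  restricted type III repertoire);
* **II** — exactly 1 in CDR1 and ≥1 in CDR3, context absent;
* **other** — anything else.

The type III criterion is a deliberate operationalisation: "conserved CDR1
context" is not a crisply published rule, so the adjacency motif is config
logic rather than biology carved in stone.

## Repertoire statistics

Collapsing counts identical full-length amino-acid sequences (nucleotide-level
dedup is an option by collapsing before translation); rank is by descending
count with a lexicographic tie-break, which makes every downstream ordering
deterministic. Abundance fractions (singletons, count < threshold) are over
*unique clones*, not reads. Box summaries use linear-interpolated quartiles
(numpy default) with 1.5×IQR fences; whiskers are clipped to the most extreme
observation inside the fences and points beyond are listed as outliers.
Sequence logos are position-frequency matrices over the 20-letter alphabet
(rows sum to 1); rendering is left to the caller. Pearson correlations come
from `scipy.stats.pearsonr`; prevalence-vs-affinity supports both raw K_D and
log10 K_D, since affinity panels typically span log-scale ranges. No
multiple-testing control is applied — single descriptive correlations only.

## Clonotype discovery

CDR3 "homology" is ungapped fractional identity between equal-length CDR3s;
thresholds are strict (identity 0.85 exactly is *excluded* by the >85% rule),
while the ≥30 clade-size rule is inclusive. `top_prevalent` deduplicates by
CDR3 string (counts summed, most prevalent carrier kept) and takes the top k
per library *before* pooling (a combined cut would let a deep library crowd
out the other; per-library cuts keep the comparison symmetric). The pooled
tree is neighbor joining (scikit-bio) on the p-distance matrix; CDR3s present
in both libraries collapse to a single dual-labelled leaf. Because the tree
is unrooted, a *clade* is defined explicitly as one side of the leaf
bipartition induced by removing an edge; `find_library_specific_clades`
enumerates all sides, keeps those with size ≥ `min_clade_size` whose fraction
of target-only leaves is ≥ `purity` (default 1.0 — a single control or shared
leaf disqualifies a side), and returns only maximal sides. Representatives
are the highest-count members (ties broken lexicographically). Sub-clustering
of a clonotype into discrete nodes is single-linkage connected components at
identity > threshold.

Defaults (`identity_threshold=0.85`, `top_k=2000`, `min_clade_size=30`,
abundance threshold 10) are the operating points of the discovery procedure
the package implements; tests and the acceptance script scale `top_k` to 500
to keep tree sizes near 10³ leaves.

## Synthetic repertoire generator

The generator emulates what the pipeline must cope with in real immunized
libraries:

* **Abundance**: clonotype counts are multinomial over Zipf weights
  (exponent 1.05 over 25 000 background clonotypes at 50 000 reads/library by
  default). A configurable read fraction (default 0.15) goes to expanded
  clonotypes private to each library, split equally among them so each planted
  clonotype has a guaranteed, comparable variant pool; the background
  clonotype set is shared between the two libraries with independently
  sampled counts.
* **Diversity**: each read of a clonotype independently acquires per-position
  substitutions (rate 0.002, ×10 inside CDR3). Unmutated reads stack on the
  centroid; mutated reads scatter into mostly-unique variants. This
  per-read model is what lets a strong abundance head (top clone ~1.6×10³
  reads at default scale) coexist with a ~90% singleton tail — a geometric
  count-split across a fixed variant set was tried first and cannot produce
  both, because geometric weights are light-tailed. At default settings the
  target library shows ≈0.90 singleton fraction and ≈0.99 below-10 fraction.
* **Architecture**: scaffolds share fixed framework blocks whose landmarks
  match the default `NumberingScheme` exactly (canonical cysteines at indices
  21 and 80, FR4 motif `WGQGT`); CDR1/HV2/HV4/CDR3 are drawn cysteine-free
  and the subtype-defining cysteines are planted explicitly, so planted
  subtype labels are exact. CDR3 draws containing the FR4 motif are rejected
  and redrawn to keep delimitation unambiguous. CDR3 lengths follow a
  triangular distribution peaked at 14 over 5–25 aa with a 0.2% ultralong
  tail (81–85 aa). The subtype mixture defaults to the Type II-dominated
  composition of an antigen-driven response (I 0.12, II 0.60, III 0.08,
  IV 0.20).
* **Reads**: reverse translation uses one fixed codon per amino acid so
  nucleotide dedup coincides with amino-acid dedup; inserts are wrapped in
  the conserved flanks, strand is random per read, and contamination is
  injected per read through mutually exclusive channels — frameshift (single
  base deletion, default 5%) and internal stop (codon replaced by TAA,
  default 2%) — with substitution-only sequencing errors (default 10⁻³ per
  base) on top. With sequencing errors disabled, the filter counters, the
  rejection reason of every contaminated read, and the clean clone table are
  exactly predictable from the truth records, and the test suite asserts
  exact equality.

What the generator does **not** emulate: germline V(D)J segment structure and
real somatic hypermutation spectra, PCR chimeras and indel sequencing errors,
codon-usage variation (single-codon reverse translation), and inter-animal
background divergence (the shared-background assumption is what makes the
control library informative; two unrelated real libraries would share almost
nothing). Passing tests therefore demonstrate the pipeline's correctness and
its discrimination of planted expansion signals — not performance on any
particular real library.

## Numerical and engineering choices

* Anchor search uses exact `str.find` when no mismatches are allowed and a
  vectorised sliding-window Hamming scan otherwise; leftmost match wins.
* All randomness flows through one `numpy` Generator seeded from
  `SimulationParams.seed`; identical parameters give byte-identical FASTQ
  (gzip written with `mtime=0`).
* p-distance matrices are computed in blocks to bound peak memory; leaf ids
  are the CDR3 strings themselves (unique after pooling).
* Degenerate inputs raise early with machine-readable messages
  (`empty_dataset`, `length_mismatch`, `degenerate`, configuration
  validation errors), and the pipeline wraps stage failures in distinct
  `PipelineError`s with non-zero exit from the CLI.

## Problem sizes

The test suite and the acceptance script run at desk scale: filtering truth
is checked at 10⁵ reads, subtype agreement at 10⁴ planted clones,
clonotype-recovery at 20 (tests) / 10 (script) simulated library pairs of
2×10⁴ reads with `top_k=500`, and the oracle-equivalence checks at ≤32-leaf
instances over 100 random cases. The full suite completes in a few minutes on
one CPU.

## Known limitations

* Region delimitation assumes the canonical-cysteine windows of the default
  scheme; heavily mutated or unusually numbered VNARs fall into the
  unannotated pool (a few percent at default simulator settings, e.g. when a
  mutation destroys the FR4 motif or a canonical cysteine).
* Clade counts on real data depend on the tree-building method; neighbor
  joining on p-distance is a standard, stated choice, but other distance or
  inference choices can split or merge borderline clades.
* Ungapped identity restricts clonotype comparison to equal-length CDR3s by
  design; length-variant members of a biological clonotype are not captured.
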