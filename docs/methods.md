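# Methods

## Model and rationale

The pipeline treats a one-against-many complex-prediction screen as a
family-detection problem. A single model's confidence scores cannot reliably
separate a true binder from a spurious high-scoring interface, but a true
binder's homologs tend to reproduce the same binding topology with similar
scores. The pipeline therefore (i) discards models whose interface the
predictor itself distrusts, (ii) reduces each surviving complex to the
regions that are confidently positioned *relative to the partner chain*,
(iii) groups the trimmed targets by sequence and by fold, joins the two
groupings, and (iv) ranks the joint clusters by size and internal structural
consistency. The method presumes the screen contains several homologs of the
true binder; with fewer than about four (the default `min_cluster_size`), no
supporting cluster can form and the approach is expected to fail — that is a
documented property of the strategy, not a bug.

## Interface confidence and trimming

PAE entry (i, j) is the expected positional error of residue i when the
model is superposed on residue j. The inter-chain block measures how well
the relative placement of the two chains is determined. Because PAE is
asymmetric, the block is symmetrized with an elementwise minimum of the two
orientations; a residue's interface confidence is then its minimum over all
partner-chain residues. This is deliberately optimistic (a single confident
partner residue suffices): trimming should keep any region the predictor
pins to the partner, and the later clustering is robust to a few extra
residues.

Trimming parameters (all CLI-exposed):

| parameter     | default | meaning |
|---------------|---------|---------|
| `pae_cutoff`  | 12 Å    | seed residues must have confidence ≤ cutoff |
| `max_gap`     | 5       | unconfident gap bridged between seed runs |
| `min_segment` | 10      | minimum bridged run length (before padding) |
| `pad`         | 2       | residues of context added per kept run |

The cutoff sits between the clearly-confident (< 5 Å) and
clearly-unconfident (> 20 Å) regimes of typical PAE matrices; `min_segment`
suppresses isolated spurious contacts while keeping any compact interacting
domain; the order of operations is bridge → drop short → pad → merge
overlaps. Trimming is idempotent and monotone in the cutoff (property
tested). Both chains are trimmed with the same parameters; a complex whose
bait or target retains nothing is discarded and recorded with a reason in
`discarded.csv`.

## Pairwise structural alignment

Cluster members are homologs by construction of the clustering step, so the
aligner is sequence-seeded rather than sequence-independent: the residue
correspondence comes from a global Needleman–Wunsch alignment (BLOSUM62,
linear gap penalty −6, deterministic traceback with tie precedence
diagonal > up > left). On that correspondence the superposition is refined
iteratively: Kabsch on the current pair subset, then keep pairs closer than
max(4.5 Å, d0), repeat to a fixpoint or 20 iterations. d0 in the cutoff is
taken at the shorter chain's length (the stricter of the two choices); if
fewer than three pairs would survive, the three closest are kept so a
superposition always exists. TM-scores are computed over *all*
correspondence pairs under the final superposition, normalized once by each
chain's length; RMSD is reported over the final kept subset. Fewer than
three matched residues yields an explicitly undefined result (carried as
missing, excluded from medians) rather than a fabricated number.

A full sequence-independent aligner (3Di alphabets, fragment assembly) is
out of scope; consequently cross-fold TM-scores here reflect the
sequence-seeded correspondence and sit well below the 0.5 same-fold
convention, which is the behavior the clustering relies on.

## Clustering and merging

Both clusterings are greedy-incremental over members sorted by (length
descending, id ascending): each member joins the first founder it matches,
else founds a new cluster. The longest family member therefore anchors its
cluster, and results are order-deterministic and invariant to input
permutation. Membership tests: sequence identity ≥ `min_id` (0.30) computed
as matches / alignment columns (gaps counted) with bidirectional span
coverage ≥ 0.8; or TM-score ≥ `min_tm` (0.5), shorter-chain normalized, with
coverage ≥ 0.8. The thresholds are the conventional homology-level values
for the two criteria. Sequence and structure clusters sharing at least one
member are merged via connected components of the bipartite cluster graph;
merged clusters are labeled by their lexicographically smallest member.

Within each merged cluster of two or more members an all-vs-all alignment
table is computed (parallelizable over worker processes; results are
byte-identical for any worker count). Each member's median RMSD and median
TM (normalized by that member) are taken over its defined pairs; the
representative minimizes median RMSD, ties broken by higher median TM, then
smaller id. Singleton clusters keep their sole member as representative
with missing medians — never zero-filled.

## Ranking, subclustering, viewer output

Ranking is lexicographic — size descending, representative's median RMSD
ascending, median TM descending, representative coverage descending, label —
because the factors are ordinal in importance: a large, low-RMSD cluster is
the method's positive signal. A weighted composite score is available behind
a parameter but off by default. Clusters below `min_cluster_size` (default
4) are excluded from ranking but remain in the audit tables.
"Representative coverage" is implemented as the representative's median
pairwise alignment coverage within its cluster.

Subclustering re-runs the greedy fold clustering *within* a top cluster at a
stricter TM threshold (default 0.7) on the concatenated bait+target CA
trace. Using the whole complex rather than the target alone is deliberate:
two binding poses of the same target fold differ only in bait-relative
placement, which the combined trace exposes and the target-only comparison
cannot.

Viewer output is a plain-text PyMOL command script per top cluster
(deterministic, diffable, viewer-optional) that loads each member, applies
the stored member-onto-representative rigid transform as a 4×4 matrix,
colors bait chains blue and target chains gray, and groups the objects.

## Synthetic screens

The generator emulates the screen layout end to end with planted ground
truth. Reference conditions: 3 binder families × 12 members, 50 decoys, a
40-residue bait, 60-residue targets whose residues 10..49 form the
interface, 0.5 Å Gaussian coordinate noise within a family, 10% per-residue
mutation off a random family consensus, ipTM 0.85 ± 0.02 for true members
and 0.50 ± 0.02 for decoys against the 0.75 gate. Chain lengths were chosen
as the smallest that leave a trimmed target (44 residues at default padding)
long enough for stable TM statistics; the ipTM centers put true members and
decoys comfortably on either side of the default gate, emulating a screen
where the gate works as intended.

Fold families are parametric CA traces — ideal α-helix (1.5 Å rise, 2.3 Å
radius, 100°/residue), antiparallel β-hairpin (3.3 Å rise with a ±0.95 Å
pleat, 4.8 Å strand separation), and helix–turn–helix variants with
family-specific turn geometry — all with consecutive CA–CA distances in
[3.7, 3.9] Å. PAE matrices are uniform background noise in 25–30 Å with the
inter-chain interface block drawn from 2–6 Å in both orientations; no
attempt is made to model realistic PAE textures, since the pipeline only
thresholds the block. Each complex draws from its own random stream seeded
by (screen seed, complex index), so generation is byte-reproducible and
subsets are stable.

What the fixtures do **not** emulate — and hence what passing tests do not
show about real data: physically realistic backbones and side chains,
partial or discontinuous interfaces, disordered regions, paralog families
with domain rearrangements, correlated PAE texture, and score distributions
that overlap the gate. The end-to-end tests demonstrate that the machinery
recovers planted family structure exactly under the stated conditions, not
that any particular ipTM or PAE threshold is optimal for a given real
screen.

## Numerical and degenerate-input choices

* Kabsch uses SVD with the standard determinant correction, so reflections
  are never returned; fewer than three points or mismatched sets raise.
* All tie-breaks (traceback precedence, greedy founder order, representative
  ties, ranking ties) are fixed and documented, making every stage
  deterministic; parallel all-vs-all preserves bitwise determinism because
  pair jobs are computed independently in a fixed order.
* CSV floats are formatted to four decimals; missing medians are empty
  fields; JSON transform files store full-precision floats so a save/load
  round trip is exact.
* Problem sizes in the test suite and acceptance script (3×12 + 50
  complexes, 40/60-residue chains) are the reference conditions above; the
  all-vs-all step dominates cost and scales quadratically in cluster size,
  linearly reducible with `cpus`.

## Known limitations

* The aligner's sequence seeding under-scores structurally similar but
  sequence-divergent pairs; within merged clusters (homologs by
  construction) this is benign, but the TM values are not interchangeable
  with sequence-independent aligners' output.
* Greedy clustering is order-dependent by design (deterministic, but not a
  global optimum); very heterogeneous families may fragment near the
  thresholds.
* One model per complex is used (the ranking file's best); alternate
  conformations of the same pair are not aggregated.
* mmCIF input and multi-model coordinate files are unsupported; exactly two
  chains (bait first) are required.
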