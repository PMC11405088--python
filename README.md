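# binderclust

Identify plausible true binders in a one-against-many AlphaFold-Multimer
screen by clustering, ranking and visualizing conserved binding topologies.

## The problem

Deep-learning complex prediction makes *in silico* pull-downs feasible: model
one bait protein against every protein of a proteome and look for confident
interfaces. At that scale, however, no single confidence score (ipTM, pDockQ,
interface pLDDT, ...) separates biologically relevant interactions from false
positives — the true binder is routinely out-ranked by dozens of spurious
high-scoring models. The observation this package exploits is that a real
binder rarely comes alone: its paralogs and homologs in the same proteome tend
to bind the bait in the same way with similarly good scores. A *family* of
mutually consistent binding topologies is therefore far stronger evidence than
any single model's score.

## What the pipeline does

Stage 1 — **clustering**:

1. **Gate** by interface confidence: keep models with ipTM ≥ threshold
   (default 0.75, inclusive).
2. **Trim** each complex with the inter-chain block of the predicted aligned
   error (PAE) matrix. A target residue's interface confidence is
   `min_i min(PAE[i, j], PAE[j, i])` over bait residues `i`; residues at or
   below the PAE cutoff (default 12 Å) seed kept segments, small gaps are
   bridged, short segments dropped, and a little padding added. The bait is
   trimmed symmetrically. Only the confidently positioned interacting
   regions survive.
3. **Cluster** the trimmed targets twice — by sequence (greedy incremental,
   identity ≥ 0.30 and coverage ≥ 0.8 against the cluster founder) and by
   fold (same greedy scheme with TM-score ≥ 0.5, shorter-chain normalized).
   Sequence and structure clusters sharing members are **merged** into joint
   clusters (connected components of the bipartite cluster graph), which
   catches remote homologs either criterion alone would miss.
4. **Representative selection**: an all-vs-all structural alignment within
   each merged cluster; the representative is the member with the lowest
   median RMSD against all others.

Stage 2 — **ranking and visualization**: clusters are ranked by size, then
median RMSD, median TM-score and representative coverage; each top cluster
gets a directory of trimmed models plus a PyMOL command script that superposes
every member onto the representative (bait blue, target gray). Optionally the
top clusters are subclustered by fold at a stricter TM threshold, on the whole
bait+target trace, to separate distinct binding poses.

The structural engine is a sequence-seeded rigid-body aligner: global
Needleman–Wunsch correspondence (BLOSUM62, linear gap −6), Kabsch
superposition, and TM-score-style iterative refinement (keep residue pairs
within max(4.5 Å, d0), re-superpose, iterate). TM-scores use the standard
normalization `TM = (1/L) Σ 1/(1 + (dᵢ/d0(L))²)` with
`d0(L) = 1.24·(L−15)^⅓ − 1.8` (floored at 0.5 Å).

## Worked example

No real AlphaFold output is needed to try the pipeline — the built-in
generator plants binder families with known ground truth:

```bash
binderclust simulate --out_dir screen --seed 11
binderclust cluster --models_dir screen --out_dir results
binderclust rank --out_dir results --subcluster
```

The simulated screen holds 86 complexes: 3 binder families × 12 members plus
50 decoys with sub-threshold ipTM. The cluster stage prints its counts:

```json
{"loaded": 86, "passed_iptm": 36, "trimmed": 36, "discarded": 0,
 "seq_clusters": 3, "struct_clusters": 3, "merged_clusters": 3}
```

All 50 decoys fail the ipTM gate; the 36 true members form exactly the three
planted families. `results/ranking.csv` then reads:

```
rank,label,size,median_rmsd,median_tm,rep_coverage,representative
1,fam2_mem00,12,1.1083,0.7973,1.0000,fam2_mem10
2,fam1_mem00,12,1.1278,0.7803,1.0000,fam1_mem09
3,fam0_mem00,12,1.1614,0.7700,1.0000,fam0_mem07
```

Each row is one merged cluster: its size, the representative's median RMSD
(Å) and median TM-score against the other members — about 1.1 Å and 0.78
here, i.e. tightly conserved topologies, as planted — and its median
alignment coverage. `results/merged_clusters/merged_clusters.csv` lists every
complex with its ipTM and ipTM+pTM scores, its sequence/structure/merged
cluster labels, per-member medians and a representative flag;
`results/rank1_*/view_cluster.pml` is a PyMOL script showing the whole
cluster superposed.

On a real screen, point `--models_dir` at a directory with one subdirectory
per complex containing `ranking_debug.json`, the best model's PDB and a JSON
score file (`iptm`, `ptm`, `iptm_ptm`, `plddt`, `pae`); the one-line
pickle-to-JSON conversion recipe is in the `binderclust.afm_io` docstring.

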