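# bicopam

Consensus co-expression module discovery across many gene expression
datasets, via tunable **b**inarization of **co**nsensus **pa**rtition
**m**atrices (Bi-CoPaM).

## The problem

A gene module that clusters together in one expression dataset may be an
artifact of that experiment. Modules that cluster together in *dozens* of
independent datasets — different labs, platforms, stresses, time courses —
are far stronger candidates for genuine co-regulation. `bicopam` finds such
modules: it clusters the same gene universe independently in every dataset
with several clustering algorithms, fuses all the resulting partitions into
one fuzzy consensus, and then tightens that consensus until only the genes
assigned *consistently everywhere* remain. It also quantifies anti-phase
behaviour: pairs of modules whose mean profiles are strongly negatively
correlated in nearly every dataset with zero lead/lag — the signature of,
e.g., growth versus stress-response programs in budding yeast.

## The method

1. **Preprocess** each genes × samples matrix: quantile normalization,
   median summarization of replicate columns into conditions, then per-gene
   z-scoring (zero mean, unit population SD).
2. **Base clustering**: each standardized dataset is partitioned into K
   clusters (default 16) by k-means with deterministic Kaufman
   initialization, a bubble-neighbourhood self-organizing map (4×4 grid),
   and Ward-linkage hierarchical clustering.
3. **Consensus (CoPaM)**: partitions are aligned by greedy *min-min*
   relabeling against the running average and averaged element-wise into a
   fuzzy K × M consensus partition matrix with column sums 1. Per-dataset
   intermediate CoPaMs are sharpened by *membership pushing* — entries of a
   gene's column below the mean of its nonzero memberships u<sub>ij</sub>
   are zeroed and the survivors renormalized — before the cross-dataset
   fusion into the final CoPaM.
4. **Tunable binarization (DTB)**: a gene is assigned to its
   maximum-membership cluster only if the runner-up membership trails by at
   least δ; otherwise it is unassigned. δ = 0 is maximum-value binarization
   (every gene assigned), δ = 1 is intersection binarization (unanimous
   genes only). Sweeping δ from 0 to 1 produces a nested family of
   ever-tighter clusters.
5. **Evaluation**: clusters are scored by the per-gene MSE
   `MSE_k = (1/(N·M_k)) Σ_{x_i ∈ C_k} ‖x_i − z_k‖²` averaged over datasets,
   ranked by the largest δ at which they retain ≥ 7 genes (larger clusters
   first on ties), and reported on an (n_genes, MSE) Pareto surface.
6. **Anti-phase analysis**: per-dataset Pearson correlation between the two
   tightest clusters' mean profiles, counts below −0.75/−0.7/−0.6, outlier
   flagging, and the cross-correlation peak lag (0 = synchronous).

A seeded synthetic-data generator produces multi-dataset collections with
two planted anti-phase modules, half-consistent confounder modules and
inconsistent background genes, so the whole pipeline is testable without
any download.

## Worked example

```python
from bicopam import GeneratorConfig, generate_collection, score_recovery
from bicopam.pipeline import RunConfig, run_pipeline, partition_at

datasets, truth = generate_collection(GeneratorConfig(seed=0))
res = run_pipeline(RunConfig(), datasets=datasets,
                   replicate_maps=truth.replicate_maps)
print(res.counts)                     # genes per cluster at each delta
print([f"C{k+1}" for k in res.ranking.top(2)])
part = partition_at(res.sweep, 0.3)
print(score_recovery(truth, part, res.gene_ids))
s = res.antiphase
print(s.counts_below[-0.75], "of", s.n_datasets, "datasets; lag", s.modal_lag)
```

prints (abridged):

```
        C1  C2  C3  C4  C5 ...
delta
0.0    160  52  89  87  66 ...
0.1    160  50  22  27  37 ...
0.3    160  50   3   2  11 ...
0.5    160  50   0   0   0 ...
1.0    153  50   0   0   0 ...

['C1', 'C2']
{'module_a': 1.0, 'module_b': 1.0}
10 of 10 datasets; lag 0
```

Reading: the two planted modules surface as clusters C1 and C2 and are the
only clusters that survive the δ-sweep (everything else — confounders and
background — empties by δ ≈ 0.4, like the mass unassignment seen in real
multi-dataset runs). At δ = 0.3 both are recovered exactly (Jaccard 1.0
against the ground truth), their mean profiles are anti-correlated below
−0.75 in all 10 datasets, and the modal cross-correlation lag is 0: they
are anti-phase with no lead or lag.

The same run is available from a shell:

```sh
bicopam synth --seed 0 --out data/
bicopam run --synth-dir data/ --out run/
bicopam ksweep --synth-dir data/ --k-values 8,16,24 --out ksweep/
```

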