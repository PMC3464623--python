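# simlabel

Semi-supervised sample labeling on similarity graphs for transcriptomic
class discovery and class prediction.

Both tasks are cast as one box-constrained quadratic program over a
sample-similarity matrix: find continuous labels `f` in `[0, 1]^N`
minimizing `(1/2) * sum_ij s_ij (f_i - f_j)^2` subject to `f = 0` on the
Class-Zero seeds and `f = 1` on the Class-One seeds. With non-negative
similarities this is a convex Laplacian quadratic form; the solver is a
fixed-point sweep (each unlabeled sample repeatedly takes the
similarity-weighted average of all labels), cross-checked by an exact
linear-system oracle. Thresholding at 0.5 gives hard calls.

* **Class discovery** seeds each split with the *most dissimilar* sample
  pair (minimal similarity, ties broken on powers of the similarity
  matrix) and recurses while any cluster's minimum within-cluster
  similarity is below a tolerance threshold, producing a binary cluster
  tree. Seed-disconnected samples ride along as transient
  pseudo-clusters and are resolved by further recursion.
* **Class prediction** uses known labels as seeds; multi-class problems
  run down a binary class tree, one-vs-all, or one-vs-one.
* **Similarity construction** covers the microarray cleaning recipe
  (clip to `[floor, ceiling]`, drop genes with `max/min <= 5` or
  `max - min <= 500`, log10), phenotype-correlated biomarker selection,
  pairwise Pearson similarity of samples, second-order
  (correlation-of-correlations) similarity, and the `[-1,1] -> [0,1]`
  linear rescaling.
* **Simulation** generates noisy block similarity matrices and
  multi-component graphs, and drives the discovery/prediction benchmark
  sweeps.

## CLI

```sh
# similarity matrix from an expression table (genes x samples TSV/CSV)
simlabel similarity --expression expr.tsv --out sim.tsv \
    --order second --scale unit --preprocess   # clip 16000/100, filter 5/500, log10

# recursive class discovery
simlabel discover --similarity sim.tsv --threshold 0.9 \
    --out-tree tree.nwk --out-assignments clusters.tsv

# class prediction from partial labels (two-column TSV: sample_id, class_id)
simlabel predict --similarity sim.tsv --labels known.tsv \
    --strategy tree --class-tree classes.nwk --out pred.tsv

# benchmark sweeps
simlabel simulate two-class --ratio 1 --ratio 5 --sigma 0.1 --sigma 0.5 \
    --reps 1000 --seed 1 --out bench.csv
simlabel simulate graph --sizes 5,5,5 --out-similarity graph_sim.tsv
simlabel simulate prediction-sweep --similarity sim.tsv --labels truth.tsv \
    --k0 1 --k0 4 --k1 1 --k1 4 --reps 1000 --out sweep.csv
```

Similarity TSVs carry a `#scale=` header so downstream stages refuse
mismatched scales; every output embeds a config hash and seed. Logs go
to stderr (`--quiet` to silence), results only to named paths.

## Layout

| module | contents |
| --- | --- |
| `simlabel.preprocess` | expression/similarity types, cleaning recipe, biomarker selection, Pearson and second-order similarity |
| `simlabel.solver` | Laplacian, fixed-point solver, exact oracle, binarization |
| `simlabel.discovery` | seed-pair selection, recursive splitting, cluster tree, summaries |
| `simlabel.prediction` | binary / class-tree / one-vs-all / one-vs-one prediction, cutoff learning |
| `simlabel.simulate` | block-similarity and component-graph generators, accuracy metric, benchmark sweeps |
| `simlabel.io`, `simlabel.cli` | file formats (TSV/CSV/Newick/YAML), run config, command-line interface |
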