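# infosig

Prioritization of **informative gene signatures** across multiple
expression datasets, scoring of their cross-dataset **eigengene
conservation**, and construction of the **functional-redundancy network**
that organizes them — with a synthetic-compendium generator so every stage
is testable without any data download.

## The problem

Gene-signature compendia (MSigDB-style collections, data-derived lists)
contain thousands of gene sets, but most of them never rank samples
robustly, and many of them are redundant in two distinct ways:
*compositionally* (large gene overlap) or *functionally* (different gene
sets reading out the same transcriptional program — possible even at zero
overlap). Both phenomena inflate multiple-testing burdens and obscure
results of enrichment analyses. This package implements an unsupervised
procedure that, given a signature collection and a compendium of
expression matrices (e.g. one per cancer type), selects the signatures
that define a natural sample ranking in several datasets at once, and then
charts their redundancy structure as a network.

Intended users: computational biologists curating signature collections or
interpreting pathway-activity analyses over multi-dataset transcriptomic
compendia (bulk or pseudo-bulk).

## The method

For a signature *S* and a genes × samples matrix *X*, PCA is applied to
the gene-centered submatrix restricted to the genes of *S* (samples as
observations). With eigenvalues λ₁ ≥ λ₂ ≥ … of the gene–gene sample
covariance:

* **L1 = λ₁ / Σᵢ λᵢ** — variance explained by the first principal
  component. *S* is **overdispersed** when L1 significantly exceeds that
  of random gene sets of the same size.
* **L1/L2 = λ₁ / λ₂** — the spectral gap. *S* is **coordinated** when this
  ratio significantly exceeds the random level, i.e. a single dominant
  axis exists.

Both statistics get empirical upper-tail p-values from random gene sets of
matched size, Benjamini–Hochberg adjusted per dataset and per statistic.
A signature is **informative** when both adjusted p-values are < 0.05 in
at least two datasets. The procedure's false-discovery rate is estimated
by running it on random signatures that mimic the input collection's size
distribution and gene multiplicities.

The first eigenvector (the **eigengene**, unit-norm gene loadings) and the
projection of centered samples on it (the **metasample**, the signature's
activity profile) support three downstream analyses:

* **conservation** — pairwise Pearson correlation of a signature's
  eigengenes between datasets; score = −mean log₁₀ of the correlation
  p-values; conserved when the geometric-mean p < 10⁻⁶;
* **redundancy** — Jaccard index of gene memberships (with hypergeometric
  overlap test) versus mean absolute metasample correlation across
  datasets (functional redundancy); a network links pairs with functional
  redundancy > 0.7, edge classes marking whether the overlap is also
  significant;
* **differential activity** — Student's t-test and activity-score
  difference between two sample groups, for coloring the map.

## Worked example

```python
import infosig as isg

spec = isg.SyntheticSpec(
    n_datasets=3, n_genes=600, n_samples=60,
    n_planted_modules=5, module_size=30, n_conserved=3,
    n_redundant_pairs=2, n_background_signatures=20, seed=7,
)
datasets, collection, truth = isg.generate_compendium(spec)

cfg = isg.ActivityConfig(n_draws=300, seed=7)
results = []
for ds in datasets:
    results.extend(isg.score_collection(collection, ds, cfg))

calls = isg.classify_informative(results, alpha=0.05, k_min=2,
                                 signature_names=[s.name for s in collection])
informative = [c.signature_name for c in calls if c.informative]
print("informative:", informative)

cons = {c.signature_name: c for c in isg.conservation_table(results)}
for name in ("MOD_01", "MOD_04"):
    c = cons[name]
    print(f"{name}: conservation score {c.score:.1f}  conserved={c.conserved}")

edges = isg.redundancy_table(results, collection, names=informative)
pair = next(e for e in edges if {e.sig_a, e.sig_b} == {"PAIR_01A", "PAIR_01B"})
print(f"PAIR_01A-PAIR_01B: Jaccard {pair.jaccard:.2f}, "
      f"functional redundancy {pair.functional_redundancy:.2f}")

graph = isg.build_graph(edges, [c for c in calls if c.informative],
                        list(cons.values()), collection, edge_threshold=0.7)
print("components:", [len(c) for c in isg.connected_components(graph)])
```

Output:

```
informative: ['MOD_01', 'MOD_02', 'MOD_03', 'MOD_04', 'MOD_05', 'PAIR_01A', 'PAIR_01B', 'PAIR_02A', 'PAIR_02B']
MOD_01: conservation score 23.7  conserved=True
MOD_04: conservation score 0.4  conserved=False
PAIR_01A-PAIR_01B: Jaccard 0.00, functional redundancy 0.97
components: [2, 2, 1, 1, 1, 1, 1]
```

All 5 planted modules and both redundant pairs are recovered as
informative while none of the 20 pure-noise background signatures is.
`MOD_01` reuses one loading vector in every dataset, so its eigengenes
correlate strongly across datasets (score 23.7, far above the
conserved threshold of 6); `MOD_04` redraws loadings per dataset and
scores near 0. The planted pair shares a latent factor but no genes:
functional redundancy 0.97 at Jaccard 0 — the dissociation the redundancy
network is built to expose. In the network (edges at functional
redundancy > 0.7) each redundant pair forms its own two-node component
and the five independent modules stay singletons.

## Command line

```bash
infosig simulate --preset default --seed 1 --out data/
infosig select   --gmt data/signatures.gmt --expr data/ --out calls.tsv
infosig fdr      --gmt data/signatures.gmt --expr data/ --nrandom 1000 --seed 1
infosig run      --gmt data/signatures.gmt --expr data/ --out results/
infosig map      --edges results/edges.tsv --calls results/calls.tsv \
                 --cons results/conservation.tsv --gmt data/signatures.gmt \
                 --format graphml --out map.graphml
infosig diff     --gmt sigs.gmt --expr expr.tsv --groups labels.tsv --out diff.tsv
```

Expression matrices are tab-separated genes × samples files (first column
gene ids, first row sample ids); signatures use the GMT format.

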