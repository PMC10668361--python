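# asvnet

Co-occurrence network analysis for amplicon (ASV) count tables: abundance /
prevalence filtering and rarefaction, Bray–Curtis + PCoA + PERMANOVA
community comparison, Spearman co-occurrence network construction,
topology metrics against Erdős–Rényi null ensembles, Zi–Pi node-role
classification (network hub / module hub / connector / peripheral), and
bootstrap Kolmogorov–Smirnov comparison of node-attribute distributions
between networks. A synthetic-community module generates grouped count
tables with planted correlation modules, connector taxa and group effects,
so every stage can be validated against known ground truth.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, analytic limits, statistical calibration, planted-structure
recovery, end-to-end determinism); the other files are per-module unit and
property tests.

## CLI

```bash
# generate a synthetic demo fixture (tables, ground truth, config)
asvnet simulate --seed 7 --out demo/

# run the whole pipeline from the generated config
asvnet run-all --config demo/config.yaml

# or stage by stage
asvnet filter    --table demo/table.tsv --out filtered.tsv --seed 7
asvnet permanova --table filtered.tsv --metadata demo/metadata.tsv --out perm.tsv
asvnet network   --table filtered.tsv --graphml net.graphml --edges edges.csv
asvnet topology  --graphml net.graphml --out topo.tsv --n-random 1000 --seed 7
asvnet roles     --graphml net.graphml --out roles.csv
asvnet compare   --graphml-a a.graphml --graphml-b b.graphml --out ks.tsv
```

`run-all` writes, per run: the filtered/rarefied table, Bray–Curtis
distance matrix, PCoA coordinates, a pairwise PERMANOVA table, one
GraphML network + edge CSV + topology summary + node-role table per
group, role-count summaries, KS comparisons for every network pair ×
{degree, betweenness, closeness}, and a JSON log recording every derived
seed and filter tally. Re-running with the same config and seed
reproduces every output byte-for-byte.

Default thresholds: 0.005% relative abundance, 30% prevalence,
|rho| > 0.7 and p < 0.05 edges, Zi 2.5 / Pi 0.62 role cutoffs, 999
permutations, 1000 random graphs, 10,000 bootstrap iterations.

## Conventions worth knowing

* Spearman p-values use the t-approximation; edge thresholds are strict
  inequalities; no multiple-testing correction by default (a
  Benjamini–Hochberg switch exists).
* Module detection is deterministic greedy modularity maximization; Zi
  uses the population standard deviation (Zi = 0 when a module's
  within-degree spread is zero); Zi/Pi values exactly on a role threshold
  fall to the lower category.
* The small-world coefficient is the Humphries–Gurney sigma
  (C/C_rand)/(L/L_rand) against a G(n, m) ensemble; path length is
  averaged over the largest connected component; closeness is
  per-component reciprocal farness; betweenness is unnormalized.
* The KS bootstrap resamples both node-attribute vectors with
  replacement at their original sizes and reports the observed D and
  asymptotic p plus a percentile interval for the bootstrap D.

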