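# stagewalk

Random-walk module discovery and evolution analysis for staged molecular
interaction networks.

Progressive diseases such as lung adenocarcinoma are usually profiled one
clinical stage at a time: each stage yields its own network of
differentially expressed genes, miRNAs and lncRNAs, with four permitted
interaction kinds (gene–gene, miRNA–lncRNA, gene–miRNA, gene–lncRNA).
Analyses that pool all stages blur exactly the differences that matter.
`stagewalk` is for researchers who want to ask, per stage: *which dense
molecular modules are active, which biological functions do they carry,
and how do both evolve as the disease advances?*

## The method

1. **Monte-Carlo walk weighting.** From every vertex of a stage network,
   R independent random walks of length N are run. Every visited step is
   recorded and weighted: the start vertex earns the basic weight *N*,
   the next step *N* − 1, down to 1 at the last step. Each visit's
   contribution to vertex *v* is divided by a degree penalty
   (deg(*v*)/d̄)^β, so aggregated weights reward being *reachable early
   from many starts* rather than simply being a hub. Vertices whose
   aggregated weight lies strictly above a quantile of the weight
   distribution are selected.
2. **Module screening.** Every pair of selected vertices is scored by the
   Jaccard-style overlap of their closed neighborhoods restricted to the
   selected set; pairs above a threshold are merged transitively, and
   each merged vertex list is split into the connected components it
   induces on the original network. Components with ≥ 5 vertices become
   modules.
3. **Stage linking.** Modules become nodes of a global module network:
   same-stage modules are linked by raw cross-edge counts, modules of
   *adjacent* stages (S1–S2, S2–S3, S3–S4) by the Jaccard coefficient
   J(A,B) = |A∩B|/|A∪B| of their member sets.
4. **Functional annotation.** Module members are tested against GMT gene
   sets with the upper-tail hypergeometric test; p-values are adjusted
   per stage by Benjamini–Hochberg, and terms with q ≤ 0.05 form a
   functional interaction network whose edges carry the Jaccard of the
   terms' gene sets.
5. **Core evolution network.** The module and function networks are
   merged (module–function edges wherever a term passed for a module).
   Modules with degree ≥ 5 in this comprehensive network are *core*
   (the threshold is motivated by comparing the below-threshold mass to
   the normal one-sigma mass, 68.26%); core functions are those adjacent
   to a core module. The core evolution network keeps inter-stage module
   edges with J ≥ 0.1 and adds function-evolution edges between adjacent
   stages for identical or similar terms.

Everything runs on synthetic fixtures with planted, drifting modules
(`stagewalk.synthdata`), so the whole pipeline is testable without any
external downloads.

## Worked example

`examples/01_recover_planted_modules.py` builds the standard benchmark
(4 planted 12-vertex modules per stage over a 40-vertex background,
intra-module edge probability 0.6 vs 0.02 elsewhere, 25% membership
drift between stages) and recovers the planted structure in stage S1:

```
S1: 88 vertices, 223 edges
selected 44 vertices above the weight quantile
  S1M1: 12 members, 39 induced edges
  S1M2: 11 members, 39 induced edges
  S1M3: 10 members, 30 induced edges
  S1M4: 8 members, 18 induced edges
adjusted Rand index vs planted truth: 1.000
fraction of planted vertices recovered: 0.85
```

An adjusted Rand index of 1.0 means every vertex the screen assigned
landed in the module of its planted lineage; coverage below 1.0 is the
deliberate effect of the weight-quantile screen. The other examples
continue the same analysis: `02` links stages (drifted lineages
reappear as inter-stage edges with J ≈ 0.3–0.6 and planted gene sets
dominate the q ≤ 0.05 screen), `03` extracts the core evolution
network, and `04` reproduces the three-design comparison on the
Q′ = −ln q scale, where testing per module (mean Q′ ≈ 10.5 on planted
terms) sharply dominates pooling whole stages (Q′ = 0).

A thin CLI wraps the same library:

```bash
stagewalk simulate --out fixture/
stagewalk walk --fixture fixture/ --out weights/
stagewalk modules --fixture fixture/ --weights weights/ --out modules.tsv
# or everything at once, from a YAML config:
stagewalk run --config config.yaml
```

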