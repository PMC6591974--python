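# rwhn

Essential-protein prediction by a **random walk with restart on a
protein–domain heterogeneous network**.

Essential proteins are those an organism cannot survive without. Because
lab-based essentiality screens are slow and expensive, computational methods
rank the proteins of a protein–protein interaction (PPI) network by predicted
essentiality. Pure topology-based centralities are brittle against the false
positives and missing edges of high-throughput PPI data; `rwhn` instead fuses
four evidence channels — interaction topology, protein-domain composition,
subcellular localization and cross-species conservation — into one network
model, for computational biologists who have a PPI network plus standard
annotation tables and want a ranked candidate list.

## Model

Three layers are built from the inputs:

1. **Weighted PPI network** — every interacting pair (i, j) gets an
   edge-clustering-coefficient weight

   WP(i,j) = |N_i ∩ N_j|² / ((|N_i|−1)(|N_j|−1))

   when both endpoints have degree > 1, else 0, where N_i is the open
   neighbourhood of i. Edges embedded in dense neighbourhoods (likely true
   interactions) get high weight.

2. **Protein–domain incidence** M_PD — binary membership of proteins in
   domain families (e.g. Pfam accessions).

3. **Domain association network** — two domains d_i, d_j with protein groups
   P(d_i), P(d_j) are linked by

   WD(d_i,d_j) = [ Σ_{y∈P(d_i)} S(y, P(d_j)) + Σ_{x∈P(d_j)} S(x, P(d_i)) ]
   / (|P(d_i)| + |P(d_j)|),  with  S(p, G) = max_{x∈G} WP(x, p).

The layers are stacked into one transition matrix: a protein spends (1−β) of
its step on its weighted PPI neighbours and β on its domains (uniformly);
domains do the symmetric thing. Rows with missing mass (isolated nodes, 0/0
normalizations) send their deficit to the restart prior — the standard
dangling-node repair.

The restart prior h₀ combines, per protein, a **functional score** (the
annotation frequency of its best compartment, relative to the most populated
compartment) and a **conservative score** (its ortholog count across
reference genomes, relative to the network maximum), averaged; each domain
inherits the maximum score of its member proteins. The walk

  h ← (1−α) · Tᵀ h + α · h₀

is iterated to its fixed point (α is the restart probability; defaults
α = 0.3, β = 0.2), and proteins are ranked by their stationary score.
Evaluation against a benchmark essential set uses top-percentage counts,
the jackknife cumulative curve (area 0.5 = chance) and precision–recall.

## Worked example

`examples/02_simulate_and_rank.py` generates a synthetic benchmark with 69
planted essential proteins whose degree, domain families, localization and
conservation are all enriched, then ranks and scores:

```
dataset: 300 proteins, 1190 interactions, 69 planted essentials
walk converged after 17 iterations
normalized jackknife area: 0.722  (0.5 = chance)
true essentials among top-ranked fractions:
  top   1%:   3 /   3 candidates (precision 1.00)
  top   5%:   9 /  15 candidates (precision 0.60)
  top  10%:  19 /  30 candidates (precision 0.63)
  ...
```

The jackknife area of 0.722 means planted essentials concentrate strongly at
the top of the ranking (1.0 would require every essential ranked first, which
the 23% essential fraction caps at ≈ 0.89); at the very top the candidate
list is pure signal. `examples/01_toy_network.py` walks a 4-protein network
whose every number is hand-checkable, and `examples/03_parameter_effects.py`
sweeps α and β.

The same pipeline is scriptable from a shell:

```sh
rwhn simulate --n-proteins 300 --seed 42 --out data/
rwhn rank --ppi data/ppi.tsv --domains data/domains.tsv \
    --localization data/localization.tsv --orthology data/orthology.tsv \
    --essential data/essentials.txt --out run/
rwhn evaluate --ranking run/ranking.tsv --essential data/essentials.txt
```

All inputs are plain TSV (`#` comments allowed): a two-column PPI edge list,
two-column protein→domain and protein→compartment tables, a two-column
protein→ortholog-count table, and an optional one-ID-per-line benchmark.

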