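# Methods

## The heterogeneous network

The method operates on n proteins and m domain families as one state space
of n + m nodes. Within the protein layer, edges are the input PPI graph
weighted by a shared-neighbourhood (edge clustering) statistic: for an
interacting pair with open neighbourhoods N_i, N_j,

    WP(i,j) = |N_i ∩ N_j|^2 / ((|N_i|-1)(|N_j|-1))   if |N_i|,|N_j| > 1, else 0.

WP is evaluated **only on input edges**; every non-edge carries weight 0.
Since adjacent i and j can share at most min(|N_i|-1, |N_j|-1) neighbours,
WP lies in [0, 1]. The statistic expresses a confidence weighting: an edge
whose endpoints share many partners is more likely to be a true interaction
and to sit inside a functional module.

Self-interactions and duplicate (unordered) pairs are removed at load time;
the graph is undirected; proteins appearing only in annotation tables are
excluded from the state space (they cannot be reached by the walk) with a
logged count.

Domain membership gives the binary n×m incidence. The domain layer is
derived: the association of a protein p with a protein group G is
S(p, G) = max over x in G of WP(x, p) (0 if no member of G interacts with p;
p contributes 0 for itself since WP has a zero diagonal), and for distinct
domains

    WD(d_i,d_j) = [ Σ_{y∈P(d_i)} S(y,P(d_j)) + Σ_{x∈P(d_j)} S(x,P(d_i)) ]
                  / (|P(d_i)| + |P(d_j)|),

a mean of maxima of WP values, hence also in [0, 1]. Domain self-weight is
fixed at 0: the association statistic is defined between distinct groups,
and a self-loop would only slow mixing. The builder evaluates all pairs
through a dense protein×domain table of S values (one sparse column-max per
domain), which is exact and keeps the double loop out of Python.

## Restart prior

Two annotation channels score each protein in [0, 1]:

* functional: each compartment's importance is its distinct-protein
  annotation count divided by the most populated compartment's count; a
  protein takes the maximum importance over its compartments.
* conservative: ortholog count (number of reference genomes with at least
  one ortholog) divided by the maximum count **among the network's
  proteins**, so counts of proteins outside the network cannot deflate
  everyone else.

A protein's raw initial score is the mean of the two; a domain takes the
maximum raw score of its member proteins (inheritance happens on raw protein
scores, before any normalization). Missing annotations score 0 — absent
evidence gives no boost, consistent with the maxima-based construction. The
concatenated (n+m)-vector is rescaled to sum to 1 so the walk state stays a
probability distribution; the fixed point is linear in the prior, so this
rescaling does not change any ranking. If every raw score is 0 the uniform
distribution is used (with a warning).

An optional filter restricts localization tables to the eleven-compartment
eukaryotic reference vocabulary (Endoplasmic, Cytoskeleton, Golgi, Cytosol,
Vacuole, Mitochondrion, Endosome, Plasma, Nucleus, Peroxisome,
Extracellular); by default the vocabulary is whatever the input contains,
keeping the method species-agnostic.

## Transition matrix and walk

Row-normalize WP, WD and the incidence (0/0 := 0). A protein with at least
one domain keeps (1−β) of its mass on its normalized WP row and sends β
uniformly over its domains; a protein without domains keeps its full WP row.
Domain rows are symmetric (β back to member proteins via the
column-normalized incidence). Rows whose mass still sums below 1 — isolated
proteins, domains with no associations, nodes whose entire layer row is
zero — have the deficit redistributed proportionally to the prior, the
standard dangling-node repair of PageRank; this is stored implicitly
(sparse raw matrix + deficit vector) so the repair never densifies the
matrix.

The walk is the standard random walk with restart

    h_{t+1} = (1-α) T^T h_t + α h0,   h_0 = h0,

with T the row-stochastic transition matrix; the transpose orientation keeps
h a distribution over nodes (mass conservation holds to 1e-10 at every
step). The map contracts the L1 distance between iterates by (1−α), so
convergence is geometric and the fixed point α(I−(1−α)Tᵀ)⁻¹h0 is unique for
α in (0, 1]; α = 0 is rejected. The iteration stops when the L1 change drops
below `tol` (default 1e-6; `max_iter` 1000 caps runaway cases and flags,
rather than fails, the result). At the defaults the walk converges in ~15–25
iterations. A direct dense solve is kept only as a test oracle — the power
iteration is the production path because it needs nothing beyond sparse
mat-vecs.

Defaults α = 0.3, β = 0.2 (yeast DIP-tuned optimum); presets for
Gavin-style networks (0.3, 0.1) and E. coli (0.2, 0.1) are exported in
`PRESETS`. Proteins are ranked by score descending, ties broken
lexicographically by ID for reproducibility; domain scores are kept as
diagnostics but never ranked.

Limit behaviours, all tested: α = 1 returns the prior exactly; β = 0
decouples the layers, so protein rankings equal a restart walk on the
weighted PPI network alone with the protein-restricted prior; m = 0 reduces
the pipeline to weighted-PPI PageRank.

## Evaluation protocols

Top-fraction counts use round-half-up for the candidate cutoff
(e.g. 1% of 1855 → 19). The jackknife curve is the cumulative count of true
essentials down the ranking; its summary area is normalized by
n · |essentials present in the ranking|, giving 0.5 in expectation for a
random ranking and a ceiling of 1 − e/n + (e+1)/2n for e essentials among n
proteins (≈ 0.885 at e/n = 0.23). Precision at cutoff K is TP(K)/K and
recall is TP(K)/|essentials present|; benchmark IDs absent from the ranking
are excluded from denominators with a logged count, since evaluation is
confined to the network's proteins. The identity precision(K)·K =
jackknife(K) is asserted in tests.

## Synthetic benchmark generator

The generator plants an essential-protein set and couples it to the four
evidence channels the method exploits; each channel has one knob whose
neutral value (1, or shift 0) makes essentiality statistically independent
of that channel. Sampling order is fixed (labels → graph → domains →
localization → orthology) under a single seeded generator, so a seed pins
the dataset byte for byte.

* **Topology** — preferential attachment (chosen over Erdős–Rényi so degree
  heterogeneity, the centrality–lethality premise, exists in fixtures); each
  new node attaches round(mean_degree/2) edges; an essential target's
  attachment weight (degree+1) is multiplied by `degree_boost`. Node arrival
  order is a random permutation so essentials are not confounded with age.
* **Domains** — half the domain vocabulary is designated
  essential-associated. `domain_enrichment` = e sets symmetric odds:
  essential proteins draw from that half at odds e:1, non-essentials at 1:e
  (both 1/2 at e = 1). A one-sided bias — only raising the essential
  proteins' preference — leaves the essential-associated groups dominated by
  the ~77% non-essential majority and plants no recoverable signal, so the
  symmetric form is used. Per-protein domain count is 1 + Poisson(0.7)
  (most proteins carry one or two annotated families).
* **Localization** — compartments are the eleven-term reference vocabulary
  with base frequencies proportional to 1/rank; essential proteins sample
  compartments from the base weights raised to `localization_enrichment`
  (concentrating them in the high-frequency compartments); every protein
  gets one compartment, a second with probability 0.3.
* **Orthology** — counts are Poisson with mean 10 (of 100 reference
  genomes) for non-essentials and 10 + `orthology_shift` for essentials,
  capped at 100.

Default conditions: n = 300 proteins, 60 domain families (the ~1:5
domain:protein ratio of the yeast DIP network), essential fraction 0.23
(DIP's 1167/5093), mean degree 8 (Gavin's 2·7669/1855), strong signal on
every channel (boost 3, domain enrichment 4, localization enrichment 3,
orthology shift +5). These sizes keep a full pipeline run under a second, so
the test suite and the acceptance script run whole benchmark sweeps (20
seeds per condition) in seconds.

What the generator does **not** emulate: false-positive/false-negative
interaction noise with structure (noise here is only sampling variation),
the empirical degree distribution of any specific interactome, correlated
multi-domain architectures, or compartment co-occurrence patterns. Passing
the planted-signal tests therefore shows the pipeline recovers the kinds of
enrichment it models, not that it attains any particular accuracy on real
interactomes.

Measured behaviour on this benchmark (recomputed by the test suite and
`scripts/acceptance.py`, never hard-coded): the null configuration averages
chance-level jackknife area, each knob raises the area monotonically, and
the default strong-signal condition reaches area ≈ 0.69 with top-1%
precision ≈ 0.95. The restart prior is the strongest single channel here;
the edge-clustering weights discard much of the planted hub signal because
preferential-attachment graphs are triangle-poor, so the topology channel
contributes least — on real interactomes, whose clustering is far higher,
the balance differs.

## Numerical and design notes

* Index ordering is lexicographic over IDs everywhere; outputs are
  deterministic for fixed inputs and parameters, byte for byte.
* WP and WD are exactly symmetric by construction (each value computed once,
  or as A + Aᵀ).
* Ranking scores are written with 12 significant digits; write→read round
  trips preserve ranks and IDs exactly and scores to 10+ digits.
* The 0/0 := 0 convention in every normalization, plus the prior-directed
  deficit repair, handles all degenerate inputs (isolated proteins, empty
  annotation tables, single-domain maps) without special cases downstream.
* Duplicate orthology rows are an error (ambiguous), while duplicate
  annotation pairs collapse silently (harmless).

## Known limitations

* The walk ranks only proteins inside the PPI network; annotation-only
  proteins are unreachable by construction.
* Evaluation treats the benchmark essential list as complete; unknown
  essentials in the negative set depress measured precision.
* The domain layer is O(m²) in memory at build time via a dense m×m
  intermediate; fine for m in the low thousands (the yeast-scale regime),
  not for hundreds of thousands of terms.
* No ID mapping between naming systems is attempted; inputs must share one
  identifier space.
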