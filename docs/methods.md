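# Methods

## Causal reasoning model

The central object is a directed graph whose edges carry a regulatory
sign (+1 activation, −1 inhibition) and a mechanism label
(transcription-regulation, phosphorylation, binding, other), and whose
nodes carry a molecular-function annotation (TF, kinase, phosphatase,
RNA, other). A hypothesis is a pair (regulator, activity sign). Its
prediction for a gene is the hypothesis sign times the product of edge
signs along the shortest paths from the regulator to the gene, restricted
to a maximum calculation distance of 1–3 edges.

Choices that the model leaves open, and how this package resolves them:

- **Only shortest paths are used.** Longer parallel paths never
  contribute, which keeps the prediction independent of path
  multiplicity and cheap to compute (layered BFS with sign sets).
- **Conflicting shortest paths make a gene ambiguous.** Ambiguous genes
  are excluded from the trial count *n* by default rather than counted
  as incorrect; this matches a correct/total reading of the score and
  keeps the binomial null well defined. `ambiguous_incorrect=True`
  switches to the punitive convention.
- **Tail, not point mass.** The hypothesis p-value is the upper-tail
  cumulative P(X ≥ k) under Binomial(n, ½). The cumulative tail — rather
  than the single-term probability mass — is what reproduces the
  published activity p-values for non-perfect scores such as 60/62 and
  19/22; for perfect scores (k = n) the two coincide at 0.5ⁿ. The tail
  is computed with exact integer arithmetic (`math.comb` against 2ⁿ), so
  values like 4.2×10⁻¹⁶ carry no accumulation error.
- **Every node is a candidate**, including nodes absent from the DEG
  table: regulators need not be differentially expressed themselves.
  Per node, the better-scoring of the two activity signs is reported;
  exact ties go to "+" and are flagged.
- **min_n = 3** by default: one- or two-gene hypotheses are never
  reported, since their minimum attainable p (0.25) is uninformative.
- **Distance-1 TF filtering** additionally requires the final edge to be
  a transcription-regulation mechanism (configurable). A distance of 1
  then means the regulator sits one step from the transcriptional event.

## Signatures

`build_signature` applies symmetric cuts: up = {log2FC ≥ +c, FDR ≤ f},
down = {log2FC ≤ −c, FDR ≤ f}; defaults c = 2.00 / 5.00 for the two
tiers, f = 0.05. `trim_signature` raises c in 0.01 increments until the
signature fits the target size (default 1100), so trimming is a strict
subset operation and the achieved cut is reported. `compute_deg_table`
offers a paired two-sided t-test on log2 expression with BH adjustment
for users starting from a matrix rather than a DEG table; genes with
zero-variance paired differences get p = 1 with a warning. Gene symbols
are upper-cased and stripped on ingest and duplicates are rejected.

## Overlap confidence scores

The score of a biomarker gene is the number of evidence lists containing
it, out of four: the biomarker list itself, the DEG set, and the causal
hub sets from the two signature tiers (so scores run 1–4). Published
overlap tables use a slightly different convention in one corner: a
biomarker that is a DEG but not a hub is printed with score 1 instead of
its membership count 2. `convention="printed"` reproduces that layout;
the default reports plain membership counts, which are monotone under
list growth.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) with
parameters (N universe, K set size, n query size), the standard ORA
convention, with BH-FDR across sets. The background universe defaults to
the union of all database sets and is configurable to the assay's
measured genes; query genes outside the universe are dropped with a
warning. Raw-p ranking is also emitted because threshold-at-0.05
workflows consume it directly.

## SPIA

Per pathway, gene-level perturbation factors solve
PF = ΔE + B·PF with B[g, j] = β(j→g)/N_ds(j), i.e. each regulator
distributes its perturbation equally over its N_ds downstream targets,
signed by β. The statistic tA = Σ (PF − ΔE). Evidence ΔE is the log2FC
of query genes; causal hubs absent from the DEG table receive
pseudo-evidence (predicted sign × median |log2FC| of the evidence),
since hub calls carry direction but no magnitude. pPERT is the add-one
corrected bootstrap fraction of |tA| values at least as large when the
same evidence values land on random pathway members (the LU
factorization is reused across bootstrap draws); pNDE is the
hypergeometric membership tail; pG combines both by Fisher's rule,
P(χ²₄ ≥ −2(ln pNDE + ln pPERT)). When I − B is singular (unit-gain
cycles, common in toy topologies), B is damped by 0.99 and the result
flagged. With all β = 0, tA ≡ 0, pPERT ≡ 1 and the ranking provably
reduces to the ORA ranking — a useful end-to-end sanity check.

## Connectivity scoring

The query is the n (default 50) most up- and most down-regulated genes
by log2FC, drawn from strictly positive / strictly negative fold changes
(ties broken lexicographically for reproducibility). Each half is
located in a reference ranking with the one-sided KS statistic: with t
query genes at sorted positions V(j) among n genes,
a = max_j [j/t − V(j)/n], b = max_j [V(j)/n − (j−1)/t], statistic = a if
a > b else −b. The raw connectivity score is ks_up − ks_down when the
halves disagree in direction and 0 otherwise; positive and negative
blocks are normalized to ±100 separately (the classic build-02
convention, declared in the output metadata). One asymmetry worth
noting: a list occupying the exact top scores 1 − t/n while the exact
bottom scores −(1 − (t−1)/n); the two differ by 1/n because the two
one-sided maxima are taken over different step functions.

## Synthetic studies

The generator emulates a single-contrast transcriptomic study at desk
scale. Defaults (all overridable in `SimulationConfig`):

- network: 500 nodes, Poisson out-degree with mean 3, targets chosen
  preferentially by in-degree (hub-dominated, like curated regulatory
  databases), 30% inhibition edges; function labels TF 15%, kinase 12%,
  phosphatase 5%, RNA 8%, other 60%; mechanisms track the source
  function (TFs emit transcription-regulation edges 85% of the time).
- 2 planted regulators with alternating activity signs, chosen as the
  widest-reach TFs; their activity propagates along shortest paths up to
  distance 3 (genes with conflicting signs across paths or regulators
  are left out of the signal set).
- DEG table of 800 genes: signal genes carry the propagated sign flipped
  with probability ε = 0.05, heavy-tailed magnitudes
  |log2FC| ~ Lognormal(median 2.5, log-sd 0.6) so a |log2FC| ≥ 5 tier
  stays populated, and p ~ Beta(0.5, 200); null genes (the remainder,
  50% target fraction) carry log2FC ~ N(0, 0.3) and uniform p. The Beta
  parameters are a config knob; the default is chosen so that a
  realistic share of signal genes survives BH at FDR ≤ 0.05 against the
  mostly-null background, as in strongly responding vaccine time points.
- 20 pathways (sizes 10–50), the first spiked with ~70% true signal
  genes, each with a sparse signed topology (~2 out-edges per member);
  biomarker lists with a 30% overlap share; a reference database of 20
  random rank permutations plus an exact reverser and an exact mimic of
  the query ordering.

All stages derive child RNG streams from the single seed through fixed
stage tags, so every artifact is byte-reproducible from one integer.

What the generator does **not** emulate: read-level count noise and
normalization artifacts, correlated co-expression (genes are independent
given the planted signs), time-course kinetics (one contrast only),
literature-derived edge confidence, and realistic gene symbol spaces.
Passing tests therefore demonstrate correctness of the algorithms and
recoverability under the stated noise model — not performance on any
particular real dataset.

## Problem sizes and numerics

The test and acceptance workloads run at deliberately small scale —
networks of 200–500 nodes, DEG tables of 300–800 genes, 100–500
bootstrap draws, 50–100 simulation replicates — which keeps a full run
in seconds while leaving every statistical check well-powered (the
planted-regulator recovery margin and the pPERT uniformity KS test both
pass with wide headroom). Linear systems are solved by LAPACK via
NumPy/SciPy with a condition-number guard at 10¹⁰; binomial and
hypergeometric tails come from exact combinatorics and
`scipy.stats.hypergeom` respectively; BH adjustment is
statsmodels' `multipletests`.

## Known limitations

- Shortest-path consensus ignores edge multiplicity and path weights;
  two regulators at equal distance with opposite signs silently cancel
  only in the generator's ground truth, not in scoring.
- The trimming rule is greedy on a fixed 0.01 grid; with heavily tied
  fold changes it can undershoot the target size by more than one gene.
- SPIA pseudo-evidence for hubs is a modeling convention; results for
  pathways dominated by non-measured hubs should be read accordingly.
- The connectivity normalization is relative to the strongest signature
  in the database block, so scores are comparable within one database
  run, not across databases.
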