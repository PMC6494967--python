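# Methods

## Model

`netpharm` scores the network-level agreement between a drug's
transcriptional footprint and a disease's gene signature.  Both are
represented as seed sets on a shared background PPI network; a random
walk with restart (RWR) turns each seed set into a smooth score field
over all nodes; the Pearson correlation of the two fields (the
*relevance*) measures how similarly the two signals diffuse through the
interactome; and a size-matched random-set permutation converts the
relevance into a Z-score.

The RWR stationary distribution solves

    s = (1 − r) W s + r e,    equivalently    s = r (I − (1 − r) W)⁻¹ e,

where `W` is the column-stochastic transition operator of the
unweighted network (column *j* spreads mass 1/deg(*j*) over *j*'s
neighbours), `e` is the uniform distribution over the mapped seeds, and
`r` is the restart probability.  For `r ∈ (0, 1]` the system is
strictly diagonally dominant, so the solution exists, is unique,
non-negative, and sums to 1 (mass conservation).  Power iteration from
`s₀ = e` converges geometrically at rate `1 − r`; with the default
`r = 0.7` and L1 tolerance `1e-10` this takes roughly 20–60 iterations.

The significance model treats the drug seed set as exchangeable with
any equally sized gene set: `n` repetitions (default 100) draw that many
nodes uniformly without replacement — size matching only, no degree
matching — propagate them with identical RWR settings, and correlate
with the disease field.  The report's Z-score is
`|relevance − μ| / σ` with the population (n-denominator) σ; with 100
repetitions the n vs n−1 choice moves Z by under 1%, and the convention
is echoed in every report.  `Z > 3` is the significance call; the raw Z
is always reported so users may apply their own cutoff.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `lfc_threshold` | 0.585 | strict \|log2FC\| cutoff (≈1.5-fold) for DEG filtering |
| `p_threshold` | 0.05 | strict raw p-value cutoff; no multiplicity adjustment — seeds are a ranked shortlist, not discoveries |
| `k` | 300 | top-DEG count per contrast, ranked by \|log2FC\| |
| `score_threshold` | 400 | STRING combined-score cutoff (medium confidence) |
| `restart_prob` | 0.7 | RWR teleport probability; higher keeps the field more local to the seeds |
| `tol`, `max_iter` | 1e-10, 10000 | L1 stopping rule of power iteration |
| `n_perm` | 100 | permutation repetitions behind μ and σ |
| Z cutoff | 3 | significance call in the report |

Selection precedes Entrez mapping: the top-*k* list is taken from the
full filtered table, and only afterwards intersected with the network
(the reported "overlap" is the mapped count, typically below *k*).

## Design choices

* **Ties in ranking** break by p-value ascending, then gene id, so the
  top-*k* list is a deterministic total order, invariant to row order.
* **Unweighted edges.** STRING scores gate edge inclusion but do not
  weight the walk; a confidence-weighted transition would conflate
  evidence strength with topology.
* **Largest connected component.** Guarantees min degree ≥ 1, hence a
  well-defined column-stochastic `W`; node loss is logged and recorded
  in the network stats sidecar.
* **Correlation over all nodes** (seeds included) by default, since the
  score fields are defined network-wide; `exclude_seeds=True` is
  available for sensitivity analysis.
* **Uniform null, no degree matching.** The null replaces the drug set
  with plain uniform draws; a degree-preserving null is a possible
  extension but a different test.
* **Reproducibility.** One integer seed governs an assessment.  Each
  permutation draws from a substream keyed `(seed, repetition)`, so
  enlarging `n_perm` extends the null sample without reshuffling earlier
  draws, and reports serialize byte-identically across reruns.
* **Numerics.** Text writers format floats with Python `repr` (shortest
  round-trip), so write→read→write is bit-exact.  A null σ below 1e-12
  is treated as degenerate (all permutation fields numerically
  identical) and Z-scoring refuses rather than divides.

## The synthetic-data generator

Validation runs entirely on generated data:

* **Network:** preferential attachment (Barabási–Albert, `m = 3`), which
  reproduces the heavy-tailed degree distribution of curated PPI
  networks and is connected by construction.  Synthetic node ids are
  fixed-width Entrez-style numeric strings.
* **Disease module:** a connected neighbourhood grown breadth-first
  from a random root, because real disease genes cluster in the
  interactome — network proximity, which RWR measures, must carry
  signal beyond raw set overlap.
* **Drug seeds:** `round(overlap_fraction · n_drug)` nodes from the
  disease module plus uniform draws outside it, so planted signal
  strength is a single dial.
* **DE tables:** planted genes get `log2FC = ±(2.0 + |N(0, 0.2)|)` and
  `p ~ U(0, 0.01)`; background genes get `log2FC ~ N(0, 0.2)` and
  `p ~ U(0, 1)`.  The effect sizes are chosen so the 0.585/0.05 cutoffs
  are exercised meaningfully: planted genes always pass and dominate
  the ranking, while background genes pass the joint filter at the rate
  `0.05 · P(|N(0, σ)| > 0.585)` (checked against the closed form in the
  tests).

What the generator does **not** emulate: negative-binomial count noise
and DE-model miscalibration, correlated expression within pathways,
STRING's exact degree distribution, annotation errors in alias maps.
Passing tests therefore demonstrate that the statistic behaves correctly
*given* DE tables and a network — not that any particular upstream DE
fit is sound.

## Calibration experiments and problem sizes

The suite validates the decision rule on known ground truth, at sizes
chosen to keep a laptop run comfortable while leaving Monte-Carlo error
well below the margins being tested:

* **Type-I error:** one fixed 500-node network and disease module;
  200 trials draw the "drug" set uniformly at random and run the full
  assessment (`n_perm = 100` each).  Fraction of Z > 3 is ~0–1%,
  within the ≤5% band expected of a 3σ rule.
* **Power:** 1000-node network, 50-gene disease module, drug seeds
  sharing 50% of it; Z > 3 in ≥90% of 50 trials (observed: 100%).
* **Monotonicity:** mean relevance increases strictly across planted
  overlap fractions {0, 0.25, 0.5, 1.0} (20 replicates each).
* **Oracle agreement:** power iteration matches the dense direct solve
  to <1e-8 (observed ~1e-12) on random 50–200-node graphs across
  `r ∈ {0.3, 0.5, 0.7, 0.9}`.

One caveat surfaced by the calibration design: at `overlap_fraction = 0`
the generator draws drug seeds from *non-disease* nodes only, which
biases relevance slightly below the uniform null mean (the null's random
sets do hit the module occasionally).  On small networks this can
inflate |Z| at zero overlap; the type-I experiment therefore draws its
null drug sets uniformly from all nodes, exactly matching the
permutation null's own generating process.

## Limitations

* The restart probability, normalization and convergence rule are not
  pinned by any external standard; results are reported with the full
  configuration echoed so runs are comparable.
* Pearson correlation on RWR fields is dominated by high-degree hubs,
  which score highly under any seeding; the permutation null absorbs
  much of this, but a degree-preserving null would be stricter.
* Results on real transcriptome/interactome data depend on the GEO
  series, the STRING snapshot, the DE-tool version, and the permutation
  RNG; two groups running the same nominal analysis will not reproduce
  each other's Z to the third decimal.  The package instead guarantees
  seeded reproducibility of its own runs, and echoes the full
  configuration in every report so runs are comparable.
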