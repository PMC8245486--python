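# gutassembly

Analysis of bottom-up gut-microbiota assembly from replicate colony counts.

In bottom-up colonization experiments a germ-free host (the reference system
is the nematode *C. elegans*) is fed defined sets of bacterial species —
monocultures, all pairs, trios, up to an eight-species community — and the
resulting intestinal populations are quantified as CFU per worm. The central
questions are statistical: which pairs coexist and which end in competitive
exclusion; whether pair compositions deviate from a non-interacting null
built from monoculture population sizes; whether the competition network is
hierarchical or harbors rock–paper–scissors cycles; and how far pairwise
outcomes alone predict the composition of larger communities.

`gutassembly` implements that entire pipeline as a tested library, plus a
synthetic experiment generator with known ground truth so every stage has a
parameter-recovery test without any external data.

## Core quantities

With N<sub>i|j</sub> the population of species *i* co-cultured with *j* and
N<sub>i</sub> its monoculture population:

* **Fractional abundance** F<sub>i|j</sub> = N<sub>i|j</sub> / (N<sub>i|j</sub> + N<sub>j|i</sub>);
  a pair *coexists* when the rarer species' mean fraction exceeds 2 %
  (just above the colony-counting detection limit), otherwise the minority
  is competitively excluded.
* **Relative yield** log RY<sub>i|j</sub> = ⟨log((N<sub>i|j</sub>+1) / ⟨N<sub>i</sub>+1⟩)⟩,
  estimated by joint bootstrap over co-culture and monoculture replicates;
  log RY < 0 means competition harms *i*.
* **Null expectation**: the mean of N<sub>i</sub>/(N<sub>i</sub>+N<sub>j</sub>) over all
  combinations of monoculture replicates, tested against measured pair
  fractions with Welch's t (effective null n = the smaller monoculture
  replicate count) and BH-FDR.
* **Competitive ability** ⟨F<sub>i</sub>⟩ = mean of F<sub>i|j</sub> over all opponents;
  the **hierarchy score** is the mean fraction of the higher-ability species
  over all ranked pairs (1 = strict pecking order, 0.5 = none), with a
  permutation null that reassigns the measured fractions to pair slots.
* **Predictions** for an n-species community: uninformed 1/n; monoculture
  null (normalized monoculture means); normalized arithmetic mean of pair
  fractions (the unnormalized means sum to n/2, hence the 2/3 factor for
  trios), optionally after the **assembly rule** removes species
  competitively excluded in their constituent pairs. Errors are Euclidean
  distance in the simplex / √2 or L1 distance / 2, compared against the
  replicate noise floor.

## Worked example

```python
import gutassembly as ga

gt = ga.make_ground_truth(11, mode="hierarchical", seed=11)
study = ga.simulate_study(gt, seed=11)   # 11 monos, 55 pairs, 20 trios, 1 octet

rep = ga.null_model_report(study.cfu_table)
print((rep.category == "coexistence").sum(), "of", len(rep), "pairs coexist")
print((rep.p < 0.05).sum(), "pairs reject the monoculture null at p<0.05")

M = ga.build_competition_matrix(study.cfu_table)
h = ga.hierarchy_score(M, n_perm=100_000, seed=11)
print(f"hierarchy score {h.score:.2f}, permutation p = {h.p_value:.2g}")

errs = ga.evaluate_predictions(study.cfu_table)
print(errs.groupby("method").error.mean().round(3))
```

prints

```
49 of 55 pairs coexist
40 pairs reject the monoculture null at p<0.05
hierarchy score 0.80, permutation p = 1e-05
monoculture_null    0.105
pairwise            0.029
pairwise_rule       0.029
uninformed          0.251
```

Reading: in this simulated study most pairs coexist, yet the monoculture
null fails for most of them — interactions, not monoculture fitness, set
pair compositions. The competition network is strongly hierarchical. Trio
compositions predicted from pair fractions (error ~3 %, at the replicate
noise floor of ~4 %) beat the monoculture null (~10 %) and the uninformed
baseline (~25 %) by an order of magnitude.

The numbered scripts under `analysis/` run the same pipeline as a narrative
sequence (simulate → pairwise statistics → network hierarchy → community
prediction → environment, immunity, and phylogeny comparisons), writing
tables under `results/`. A `gutassembly` CLI exposes the same stages
(`simulate`, `analyze`, `predict`, `hierarchy`, `compare-env`,
`compare-strains`, `phylo`, `recover`).

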