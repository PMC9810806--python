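# dietsel

Diet-selectivity analysis for paired gut-content / ambient-water
metabarcoding surveys.

When the diet of a small planktonic consumer (e.g. a rotifer) is read
out by 18S amplicon sequencing of its gut contents, the consumer's own
reads dominate the library and the remaining reads must be compared
against the ambient community to separate "eats what is there" from
genuine prey preference. `dietsel` implements that workflow as a tested
library plus CLI:

- **Consumer-read removal** by taxonomy match (default: genus), with
  per-sample tallies and empty-sample flagging.
- **Electivity index** `E = (r_i − p_i) / (r_i + p_i)` per taxon and
  season, where `r_i` is the taxon's relative read abundance in the diet
  and `p_i` in the ambient water; `E > +0.25` is classified as
  preference, `E < −0.25` as discrimination, the interior as
  non-selective feeding.
- **Dominance index** `Y_i = (n_i / N) · f_i` (McNaughton form:
  overall read share times occupancy).
- **Differential enrichment**: per-taxon two-sided Wilcoxon rank-sum
  tests on per-sample proportions (exact null for small tie-free
  samples), with Benjamini–Hochberg FDR control at 0.05.
- **Community comparison**: Bray–Curtis distances, rank-based ANOSIM
  with permutation p-values and the conventional interpretation bands
  (R > 0.75 large, > 0.5 medium, > 0.25 small), hierarchical cluster
  ordering for heatmaps.
- **Rarefaction** by the exact hypergeometric expectation
  `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]`, and shared/unique OTU
  (Venn) accounting.
- **Constrained ordination** written from scratch: correspondence
  analysis, DCA axis-1 gradient length (model choice: CCA above 4 SD,
  RDA below 3 SD), RDA and CCA with explained-inertia reporting, and
  greedy forward selection of environmental variables validated by
  Monte-Carlo permutation pseudo-F tests.
- A **synthetic study generator** that emulates the survey design
  (3 sites × 4 seasons, gut and water compartments, seasonal community
  succession, a dominant consumer read fraction, and trophic-state
  environmental covariates) with known ground-truth selectivity, so
  every estimator can be validated end to end.

## Worked example

Run the full pipeline on a simulated study in which chrysophyte and
synurophyte classes are ingested with preference weight 4:

```pycon
>>> from dietsel import RunConfig, run_pipeline
>>> from dietsel.simulate import study_preset
>>> report = run_pipeline(RunConfig(outdir="out", simulate=study_preset(seed=1),
...                                 seed=1, n_perm=999))
>>> report["anosim"]
{'R': 0.0446..., 'p': 0.184, 'band': 'negligible', 'n_permutations': 999}
>>> report["ordination_water"]["gradient_length"]
3.14...
>>> report["ordination_water"]["method"]
'CCA'
```

`out/electivity_table.tsv` then holds the per-class table (dominance
`Y`, one `E` per season, classification). With the preset weights the
preferred classes come out around `E ≈ 0.5–0.6` in every season
(`mean E = 0.549` over the 8 preferred class × season cells at seed 1)
and neutral classes stay near zero (`mean |E| = 0.066`), i.e. the
estimator recovers the generative selectivity. The ANOSIM `R ≈ 0.04`
says gut and water class profiles barely separate here — expected,
because the simulated diet is ambient composition reweighted by mild
preferences. The same analyses are available as CLI subcommands
(`dietsel simulate | preprocess | rarefaction | venn | selectivity |
distance | anosim | ordinate | run`).

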