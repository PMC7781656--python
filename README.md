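# soiltrace

Exposure-history analysis of soil-to-gut microbiome assembly.

`soiltrace` is a Python library for a recurring study design in gnotobiotic
microbiome research: germ-free mice are raised in contact with distinct
environmental microbial communities (here: desert, steppe and forest soils),
their gut metagenomes are profiled at a first timepoint (Day 60), the animals
are then transferred across environments, and profiled again (Day 90). The
scientific questions are (1) which environmental microbes colonize the gut and
how strongly the "birthplace" community structures it, (2) how large the
community shift after migration is and whether it depends on the birthplace,
and (3) which taxonomic and functional birthplace signatures persist after the
shift.

The library implements the full analysis from abundance tables onward, plus a
seeded synthetic-study generator with recorded ground truth so every statistic
can be validated by parameter recovery.

## What it computes

* **Gene abundance**: length-normalized copy numbers *b<sub>i</sub> =
  x<sub>i</sub>/L<sub>i</sub>* and relative abundances *a<sub>i</sub> =
  b<sub>i</sub>/Σ<sub>j</sub> b<sub>j</sub>* from mapped-read counts, with
  gene→KO (KEGG Orthology) aggregation.
* **Diversity**: Shannon index *H = −Σ p<sub>i</sub> ln p<sub>i</sub>*,
  seeded rarefaction with a hypergeometric closed-form oracle, and the
  Jensen–Shannon distance
  *JSD(P,Q) = ½KL(P‖M) + ½KL(Q‖M)*, *M = (P+Q)/2*, with base-2 logs so
  JSD ∈ [0, 1].
* **Ordination & inference**: principal coordinates analysis (classical
  scaling of the Gower-centered squared-distance matrix) and one-factor
  PERMANOVA with a permutation p-value
  *p = (1 + #{F<sub>perm</sub> ≥ F<sub>obs</sub>})/(1 + N)*.
* **Differential abundance**: per-feature Kruskal–Wallis screening with
  Benjamini–Hochberg FDR control for taxa; a negative-binomial
  likelihood-ratio test with median-of-ratios size factors and
  method-of-moments dispersions for KO counts. Each marker carries an
  enrichment direction (the group with the largest mean).
* **Pathway enrichment**: reporter Z-scores
  *Z<sub>raw</sub> = Σ Z<sub>KO</sub>/√k* corrected by the moments of random
  same-size KO sets, significance at *Z<sub>adj</sub> ≥ 2*, and ternary
  assignment of each enriched pathway to the group where most of its
  significant member KOs point.
* **Exposure history**: soil→gut colonization accounting, per-mouse
  Day-60→90 JSD with pairwise Wilcoxon group comparisons, marker persistence
  (significant at both timepoints with consistent direction), and taxon-overlap
  source attribution.

## Worked example

```bash
python examples/06_exposure_history.py
```

prints, for a synthetic study with 15 mice per group (seed 3):

```
colonization (soil species establishing in the gut):
  desert : 251/352 species (71.3%), carrying 100.0% of gut abundance
  steppe : 209/443 species (47.2%), carrying 100.0% of gut abundance
  forest : 211/290 species (72.8%), carrying 100.0% of gut abundance

mean Day-60->90 JSD by birthplace (drift after the environment shift):
  steppe : 0.059
  desert : 0.063
  forest : 0.075

persistence: 7 of 39 Day-60 birthplace markers (18%) still marked birthplace
at Day 90 with the same direction
```

Reading this: about half to three-quarters of each soil community establishes
in the gut; steppe-born mice move least after the environmental shift (the
generator's drift rates order steppe < desert < forest, and the per-mouse JSD
recovers that ordering); and roughly a fifth of the Day-60 birthplace markers
survive the shift — near the planted persistence fraction of 25%.
Each example script (`examples/01…07`) demonstrates one capability the same
way; `soiltrace run-all --seed 1 --out report.json` runs everything from the
shell.

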