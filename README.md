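# sbnet — signed Bayesian networks for microbial colonization order

`sbnet` infers directional relationships between microbial taxa from a
plain abundance matrix — no longitudinal design required — and checks
whether those directions are consistent with known colonization orders.
It is aimed at microbiome researchers who already have an OTU/taxon
abundance table (mothur-style shared file or TSV) and want more than an
undirected co-occurrence network.

## Method

Given an `n × p` abundance matrix `B` (samples × taxa), each row is
normalized to relative abundances `x⁽ⁱ⁾ = b⁽ⁱ⁾ / w⁽ⁱ⁾` with
`w⁽ⁱ⁾ = Σⱼ bⱼ⁽ⁱ⁾`, and taxa are filtered to the most abundant set whose
mean relative abundances jointly cover 99% of the mass. The pipeline
then combines three objects:

1. **Bayesian network structure (PDAG).** The order-independent
   PC-stable algorithm: start from the complete undirected graph, delete
   edges by level-wise conditional-independence testing (Gaussian
   partial correlations with Fisher's z-test, `z = ½ ln((1+r)/(1−r))`,
   or the exact Student t-test), orient unshielded triples `i−j−k` as
   colliders `i→j←k` when `j` is outside the separating set of `(i,k)`,
   and propagate orientations with the three standard rules. Edges whose
   direction is not identifiable remain undirected.
2. **Co-occurrence network (CoN).** The complete graph weighted by
   pairwise Pearson correlations of the same columns.
3. **Signed Bayesian network (sBN).** Every PDAG edge is annotated with
   its CoN correlation: green for positive, red for negative. Node size
   carries mean abundance; edge opacity carries a bootstrap support —
   the fraction of 200 learner re-runs on randomized inputs (variable
   order permuted by default) that reproduce the edge's orientation.

Against early/late colonizer labels, the evaluation module counts
directed edges early→late versus the inconsistent late→early and reports
the direction-consistency percentage
`100 · (labeled − late→early) / labeled`. A succession simulator
(logistic colonization waves with programmed handovers) provides ground
truth for end-to-end validation: consecutive colonizers are negatively
correlated during a handover, so sBN edges joining them should be red.

## Worked example

Simulate a three-class succession (Bacilli → Gammaproteobacteria →
Clostridia, the classic preterm infant gut order), then run the full
pipeline with the time line split into two periods:

```bash
sbnet simulate --out demo --seed 11 --subjects 12 --timepoints 10
printf 'Bacilli\tearly\nGammaproteobacteria\tearly\nClostridia\tlate\n' > demo/labels.tsv
sbnet all demo/abundance.tsv --times demo/times.tsv \
      --labels demo/labels.tsv --evaluate --periods 2 \
      --bootstrap-reps 200 --seed 1 --out demo/run
```

`demo/run/period1_edges.tsv` shows the first handover as a strongly
negative edge between the two earliest colonizers, reproduced in every
bootstrap replicate:

```
source   target               orientation  r          sign      support
Bacilli  Gammaproteobacteria  undirected   -0.999994  negative  1.0000
```

and `period2_edges.tsv` the second handover, now directed:

```
Clostridia  Gammaproteobacteria  directed  -0.999705  negative  1.0000
```

`r` is the Pearson co-occurrence correlation (edge width/color in
Cytoscape: red = negative), `support` the fraction of 200 permuted-input
re-runs reproducing the orientation. `consistency_report.tsv` tabulates,
per period and in total, the edge counts and the direction-consistency
percentage against the labels; `manifest.yaml` records every parameter
of the run. GraphML files import directly into Cytoscape with
`mean_abundance`, `r`, `sign`, `support` and `orientation` attributes.

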