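# retinomature

Linking gene expression in the developing zebrafish eye to the maturation of
visual function. Between 3 and 5 days post-fertilisation (dpf), zebrafish
larvae progress from essentially blind to visually responsive; genes whose
ocular expression rises or falls across this window are candidate regulators
of vision. `retinomature` re-implements, as a tested pipeline over synthetic
data, the computational chain such a study needs:

1. **Custom array re-annotation** — transcript models from several source
   databases are clustered into genes by coding-exon overlap (two
   transcripts share a gene iff they are connected, directly or transitively,
   by ≥ 1 bp of CDS overlap on one chromosome and strand); individual 25-mer
   probes are kept only if they align perfectly, uniquely, fully inside a
   CDS exon and within a single gene; survivors are regrouped into
   *transcript-level probe sets* (probes covering exactly the same
   transcript set).
2. **Differential expression** — quantile normalization, median-polish
   summarization, removal of probe sets with max log₂ intensity < 6 in all
   samples, then an empirical-Bayes moderated t-test for 5 vs 3 dpf:
   per-probe-set variances s²_g (d_g df) are shrunk toward a prior s²₀ with
   d₀ extra df, s̃² = (d₀s²₀ + d_g s²_g)/(d₀ + d_g),
   t = Δ/(s̃·√(1/n₁+1/n₂)) on d₀+d_g df. P-values are BH-adjusted; a probe
   set is called DE at q < 0.05 with linear fold change ≥ 1.5 or ≤ 0.67.
3. **Splicing-index gate** — for a gene with several probe sets,
   SI_i = log₂FC_i − median(log₂FC) over the gene's sets; if every
   |SI| ≤ 1 the probe-set expressions are averaged into a gene-level value
   and re-tested, otherwise the probe sets are reported separately as
   candidate alternative-splicing events.
4. **Cross-species enrichment and disease mapping** — best human homologs
   (≥ 30% identity over ≥ 30% of the query, highest bitscore) transfer human
   GO/KEGG annotation onto zebrafish genes; one-sided Fisher exact
   (hypergeometric upper-tail) enrichment runs per namespace with BH within
   namespace, significant at q < 0.05; DE-gene homologs are intersected with
   intervals of mapped-but-unsolved inherited retinal disease loci.
5. **Visual motor response (VMR)** — per-larva 1 Hz activity traces over a
   settle + alternating light ON/OFF protocol; the response peak is the
   maximal 1-s bin in a window after each transition, normalized to the mean
   activity before it; duplicate ON (OFF) responses are averaged per larva;
   groups are compared by Wilcoxon rank-sum (exact for small tie-free
   samples) with Bonferroni correction, or Welch's t-test.

A seeded synthetic-study generator (`retinomature.synthgen`) emulates the
whole data structure — redundant transcript models, problematic probes,
log-normal intensities with spiked fold changes and spiked discordant probe
sets, a spiked enriched pathway, disease loci with and without candidates,
and VMR traces with injected bursts — so every stage is validated against a
known ground truth without any download.

## Worked example

Run the numbered analysis steps (each a thin driver over the library):

```bash
python analysis/01_simulate.py
python analysis/02_reannotate.py
python analysis/03_differential_expression.py
python analysis/04_enrichment.py
python analysis/05_behavior.py
```

With the default seed this prints, among other lines:

```
309 transcripts clustered into 150 genes
  gene partition matches ground truth: True
probes: 2384 aligned, 2167 retained; removed by reason: {'not_exonic': 108, 'multi_hit': 55, 'mismatched': 54}
197 transcript-level probe sets over 150 genes (0 under-populated groups dropped)
197 probe sets summarized; 55 below the log2 < 6 detection floor; 142 tested
5 vs 3 dpf: 14 probe sets up, 8 down (q<0.05, FC>=1.5 or <=0.67)
splicing gate: 3 genes discordant (reported per probe set), 115 aggregated to gene level
up: 11 genes, 51 terms tested, 1 significant at q<0.05
  top term: KEGG:99999 (cytokine signalling cascade), 8/23 genes, q=9.73e-04
disease mapping: 12 loci, 8 candidate gene-locus pairs (6 diseases with candidates)
norm_on: treated 4.27 vs control 8.63 (decrease); Wilcoxon p=0.0022, Bonferroni-adjusted 0.0087
```

Reading this: the overlap clustering reconstructs the simulated gene models
exactly; the probe filter removes precisely the multi-hit, mismatched and
non-exonic probes; 22 probe sets change between 5 and 3 dpf, the spiked
signalling pathway is the single enriched term among up-regulated genes, and
the simulated drug treatment roughly halves the larvae's normalized light-ON
response (fold increase 8.6 → 4.3).

The same chain is available as a CLI
(`retinomature simulate|annotate|remap|de|vmr|run`); `retinomature run
--config run.yaml` executes everything from one YAML file and writes a
manifest of input/output hashes, so a rerun on identical inputs is
byte-identical.

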