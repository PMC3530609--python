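# Methods

This note records the models, estimators and design choices behind
`retinomature`, and what the synthetic validation does and does not show.

## Re-annotation model

Transcripts are CDS-exon interval sets in 0-based half-open coordinates
(GFF3's 1-based inclusive convention is converted at I/O). Gene clustering
is the connected-components closure of the pairwise relation "shares ≥ 1 bp
of CDS overlap on the same chromosome and strand". Strand is respected by
default because antisense transcripts overlapping a locus are biologically
distinct genes; `--ignore-strand` disables this. The implementation is a
sweep line over exon intervals with union-find (O(n log n)); an O(n²)
all-pairs brute-force oracle ships in the package and the test suite checks
equivalence on hundreds of random instances. Gene ids are assigned after
sorting clusters by (chromosome, hull start, smallest member id), so the
labelling is deterministic and input-order invariant.

Probe filtering keeps a probe iff it has zero mismatches, exactly one
genomic hit, lies entirely within a CDS exon, and every transcript
containing it belongs to one gene cluster. This is the strictest defensible
reading of "problematic probes removed" — the reason for each removal is
logged (`mismatched`, `multi_hit`, `not_exonic`, `multi_gene`). Probe sets
are formed per gene by grouping probes on their exact covered-transcript
set; the default minimum of 3 probes per set exists because a median polish
over fewer rows is statistically meaningless, and is exposed as
`--min-probes`.

Homolog filtering keeps hits with identity ≥ 30% and aligned length ≥ 30%
of the query (both inclusive), then takes the highest bitscore per query
(ties: lowest e-value, then lexicographic subject). Annotation transfer is
a union: a zebrafish gene gains every term of its best human homolog.
Homolog queries may be transcript ids (a blastx of cDNAs); the pipeline
folds them onto gene clusters, keeping the best-scoring member hit.

## Expression model and moderated test

Normalization is quantile normalization on log₂ intensities: each column's
sorted values are replaced by the across-column mean of sorted values; ties
within a column receive the mean of the reference values mapped onto them,
so the procedure is exactly idempotent. This is a deliberate simplification
of sequence-affinity background models: those require probe sequences,
which carry no information in this pipeline (probes are represented by
alignment coordinates only).

Summarization is two-way median polish of each probe set's probes × samples
log₂ sub-matrix (10 iterations max, relative tolerance 1e-6); the reported
value per sample is overall + column effect, which absorbs probe affinity
into discarded row effects. The detection filter then removes probe sets
whose maximum summarized log₂ value is < 6 in every sample (strict
inequality; a max of exactly 6 is kept).

The moderated t-test follows the standard empirical-Bayes hierarchy:
s²_g | σ²_g ~ σ²_g·χ²_{d_g}/d_g with 1/σ²_g ~ χ²_{d₀}/(d₀s²₀). The prior
(d₀, s²₀) is estimated by matching the mean and variance of log s²_g using
digamma/trigamma identities, with the trigamma equation solved by Newton
iteration; when the empirical dispersion of log s²_g falls below its
theoretical sampling floor the prior degrees of freedom are infinite and
every variance shrinks to s²₀ (t is then referred to a standard normal).
d₀ = 0 reproduces the ordinary pooled t exactly, which the tests assert
against scipy, and the full chain matches the Bioconductor `limma::eBayes`
reference to ~1e-8 on a shared dataset. Zero-variance rows are floored at
1e-10 with a warning. BH adjustment is the step-up procedure via
statsmodels; the tests check it against an exhaustive min-over-suffix
oracle. DE calling requires q < 0.05 *and* a linear fold change ≥ 1.5 or
≤ 0.67 — the asymmetry (log₂ 0.585 vs −0.578) is kept exactly as stated,
and the fold change is 2^(difference of mean log₂ values).

The splicing index is fold-change-centred: SI_i = log₂FC_i minus the
*median* probe-set log₂FC of the gene (mean-centring is available via the
`center` argument). Median centring makes the gate robust when one of two
probe sets carries the aberration; single-probe-set genes have SI = 0 by
definition. Genes passing the gate (all |SI| ≤ 1) have their probe-set
expression rows averaged per sample and are re-tested at gene level, with
BH recomputed over the gene-level tests — multiplicity is defined by the
reported unit. Gene-level q-values are therefore not inherited from the
probe-set level.

Sample clustering z-scores rows (zero-variance rows dropped and counted),
uses 1 − Pearson correlation between samples, and average linkage through
scipy; an independently coded O(n³) UPGMA oracle bounds the merge heights
to 1e-10 in the tests. The dendrogram is exported as newick.

## Enrichment and disease mapping

Enrichment is the one-sided hypergeometric upper tail
p = Σ_{x≥k} C(K,x)C(N−K,n−x)/C(N,n) per term; only enrichment is tested
(the tables of interest report over-representation). The universe defaults
to genes represented by probe sets surviving the detection filter — the
entities actually measured — rather than all annotated genes; this is a
documented choice, configurable by passing a different universe. BH runs
within each namespace (GO BP/CC/MF, KEGG) because results are reported per
category. No GO-graph ancestor propagation is performed; the catalog is
taken as given.

Disease loci are intervals on the human genome, either given directly or
resolved from cytogenetic band strings (`6q14-q16.2` → start of the first
matching band to end of the last, against a UCSC-format band table). A DE
gene is a candidate for a locus when its mapped homolog's interval overlaps
the locus by ≥ 1 bp, including straddling the boundary.

## VMR quantification

Traces are 1 Hz per larva (sub-second data are integrated into 1-s bins by
summation, light state by majority). Per light transition after the settle
period, the peak is the maximal 1-s bin within 30 s after the transition
(a windowed mean is available via `peak_mode`) and the baseline is the mean
over 30 s before it; the window lengths are conventions — transient bursts
decay within seconds — and both are flags. Duplicate ON (OFF) responses are
averaged per larva *before* any group statistic. Normalized peaks average
per-transition peak/baseline ratios; transitions with zero baseline
(immobile larvae) are skipped rather than producing infinities, and larvae
whose every baseline is zero report NaN and are excluded (and counted) in
group tests. The rank-sum test uses the exact null for combined n ≤ 20
without ties and the tie-corrected normal approximation otherwise;
Bonferroni multiplies by the number of comparisons in the report.

## Synthetic study: what it emulates

Defaults encode the study design: three stages (3/4/5 dpf) × three
biological replicates, 11 probes of 25 nt per probe set, 2,000 probe sets,
7.5% of probe sets spiked at |log₂FC| = 1.5 (assigned gene-coherently —
expression change without splicing moves all of a gene's probe sets
together), probe-level noise SD 0.35, 10% of multi-probe-set genes spiked
with ±1.25 discordance (so |SI| = 1.25 by construction), 10% of probe sets
at low baseline to exercise the detection filter, a 30-gene spiked pathway
at 50% DE membership, and a VMR protocol of 30 min settling plus four
20-min ON/OFF cycles at baseline rate 0.1 and burst amplitude 0.9.
Intensities are log₂-normal: probe-set baselines Uniform(4, 12) (low sets
Uniform(2, 4.5)), per-probe affinity offsets Normal(0, 0.8) drawn once, the
stage effect realized fully at 5 dpf and half at 4 dpf (gradual
maturation), noise i.i.d. Normal(0, 0.35); export is linear-scale. Values
the design leaves open were chosen once as field-realistic: 25 chromosomes
(zebrafish karyotype), 80% homolog coverage, 12 larvae per group, treated
burst amplitude scaled by 0.4, log-normal amplitude jitter SD 0.15. One RNG
stream per output family, all spawned from the master seed, makes equal
configs byte-identical and lets one family be regenerated without
perturbing others.

Deliberately **not** emulated: probe GC-content affinity bias (hence no
sequence-based background correction), array spatial artefacts, stage-
dependent variance, correlated noise between probes, video-level behaviour
data. Passing tests therefore demonstrate correctness of the computations
and recovery under the stated noise model, not robustness to real-array
artefacts.

## Validation sizes and numerical choices

The repeated-simulation checks use sizes chosen for desk-scale runs: the
DE error-rate check averages 20 seeds of the 2,000-probe-set default (the
acceptance script uses 10), the splicing-gate check 10 seeds of 400 probe
sets at noise SD 0.1, the enrichment-recovery check a 3,000-gene universe
with 300 DE genes over 20 seeds (script: 10), and prior recovery n = 5,000
variances (observed error ≈ 2%, well inside the 15% band). Oracles:
exhaustive BH for ≤ 8 p-values, direct hypergeometric summation for
N ≤ 60, brute-force clustering for ≤ 200 transcripts, naive UPGMA, and full
rank-sum enumeration for combined n ≤ 12.

Known limitations: the probe filter's criteria and the minimum-probe
threshold are documented conventions rather than reconstructions of any
specific platform's rules; the splicing-index centring (median) is likewise
a documented convention; quantile normalization assumes globally comparable
intensity distributions and will distort if a large asymmetric fraction of
the transcriptome truly changes; the enrichment universe choice materially
affects p-values and should be revisited for real data.
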