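"""Synthetic study generator.

Emulates the data structure of a three-stage (3/4/5 dpf) zebrafish eye
microarray study so every pipeline stage can be exercised and validated
against a known ground truth, without any external download:

* redundant transcript models from multiple "source databases", overlapping
  within a gene and separated by gaps between genes;
* 25-mer probe alignments — mostly unique perfect exonic hits, plus a
  configured fraction of problematic probes (multi-hit, mismatched,
  intergenic, exon-boundary-spanning) whose intended filter outcome is
  recorded;
* a log2-normal intensity model: probe-set baselines Uniform(4, 12) (a low
  fraction drawn at (2, 4.5) to exercise the detection filter), per-probe
  affinity offsets drawn once, spiked log2 fold changes at 5 dpf (half
  effect at 4 dpf) for a fraction of probe sets, discordant spiked fold
  changes within flagged multi-probe-set genes (alternative splicing), and
  Normal(0, noise_sd) noise; exported on the linear scale;
* GO/KEGG-style gene-set catalogs on both species' sides, a homolog table
  with hits straddling the 30%-identity / 30%-length filter boundary, one
  spiked enriched pathway, and disease loci that do and do not contain DE
  gene homologs;
* 1 Hz larval activity traces over a 30 min settle + four 20 min ON/OFF
  cycle protocol, with bursts of known amplitude injected at each light
  transition over a Poisson-like baseline.

One RNG stream per output family, all spawned from the master seed, so the
same ``SimConfig`` always yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .reannotate import TranscriptRecord
from . import io as rio

_SOURCES = ("ensembl", "genbank", "zfin")

GO_CATEGORIES = (
    "Adhesion", "Cell cycle", "Death", "Development",
    "Muscle development and system process", "Regulation",
    "Response to stress/stimulus", "Signal transduction",
    "Transcription", "Transport", "Vision and light stimulus",
)

_GENE_PITCH = 3000      # bp between gene starts on a chromosome
_CORE_LEN = 300         # shared CDS exon length
_EXTRA_OFFSET = 600     # start of the transcript-specific exon
_EXTRA_LEN = 300


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ["annotation", "probes", "expression", "functional", "behavior"]
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class AnnotationTruth:
    transcripts: list[TranscriptRecord]
    transcript_gene: pd.DataFrame          # transcript_id, true_gene
    genes: pd.DataFrame                    # true_gene, chrom, strand, start, multi_probeset
    probe_regions: pd.DataFrame            # true_gene, probeset_label, chrom, strand, start, end, transcripts


def gen_genome_annotation(config: SimConfig) -> AnnotationTruth:
    """Lay out genes on chromosomes and emit redundant transcript models.

    Each gene owns a core CDS exon shared (with random flank jitter) by all
    of its transcripts, guaranteeing within-gene overlap; genes are spaced
    far apart so no two genes' exons can touch.  Genes flagged
    multi-probe-set carry a second transcript with an additional private
    exon, which downstream probe grouping resolves into a second,
    transcript-specific probe set.
    """
    if config.n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = _streams(config)["annotation"]
    lo, hi = config.transcripts_per_gene

    transcripts: list[TranscriptRecord] = []
    tg_rows, gene_rows, region_rows = [], [], []
    for i in range(config.n_genes):
        gene = f"TG{i + 1:05d}"
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        g0 = 10_000 + (i // config.n_chromosomes) * _GENE_PITCH
        strand = "+" if rng.random() < 0.5 else "-"
        multi = bool(rng.random() < config.frac_multi_probeset_genes)
        tpg = int(rng.integers(lo, hi + 1))
        if multi:
            tpg = max(tpg, 2)

        tids = []
        for j in range(tpg):
            tid = f"{gene}.t{j + 1}"
            tids.append(tid)
            # redundant models differ only by a left flank extension; the
            # right edge is shared so probes straddling it stay non-exonic
            jit_l = int(rng.integers(0, 80)) if j else 0
            exons = [(g0 - jit_l, g0 + _CORE_LEN)]
            if multi and j == 1:
                exons.append((g0 + _EXTRA_OFFSET, g0 + _EXTRA_OFFSET + _EXTRA_LEN))
            transcripts.append(TranscriptRecord(
                transcript_id=tid, source_db=_SOURCES[j % len(_SOURCES)],
                chrom=chrom, strand=strand, cds_exons=tuple(exons)))
            tg_rows.append({"transcript_id": tid, "true_gene": gene})

        gene_rows.append({"true_gene": gene, "chrom": chrom, "strand": strand,
                          "start": g0, "multi_probeset": multi, "n_transcripts": tpg})
        region_rows.append({"true_gene": gene, "probeset_label": "a",
                            "chrom": chrom, "strand": strand,
                            "start": g0, "end": g0 + _CORE_LEN,
                            "transcripts": ";".join(tids)})
        if multi:
            region_rows.append({"true_gene": gene, "probeset_label": "b",
                                "chrom": chrom, "strand": strand,
                                "start": g0 + _EXTRA_OFFSET,
                                "end": g0 + _EXTRA_OFFSET + _EXTRA_LEN,
                                "transcripts": tids[1]})
    return AnnotationTruth(
        transcripts=transcripts,
        transcript_gene=pd.DataFrame(tg_rows),
        genes=pd.DataFrame(gene_rows),
        probe_regions=pd.DataFrame(region_rows),
    )


def gen_probe_alignments(
    config: SimConfig, annotation: AnnotationTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place 25-mer probes in the annotated exons, plus problematic probes.

    Clean probes (mismatches 0, a single genomic hit, entirely inside a CDS
    exon) fill each probe-set region; a configured fraction of extra probes
    cycles through the failure modes multi_hit / mismatched / intergenic /
    boundary, and the truth table records each probe's intended filter
    outcome.

    Returns (alignment table, probe truth table).
    """
    rng = _streams(config)["probes"]
    plen = config.probe_length
    if annotation.probe_regions.empty:
        raise ConfigurationError("no exon regions to place probes in")

    aln_rows, truth_rows = [], []
    counter = 0

    def add(chrom, strand, start, mism, hits, kind, retained, region_id):
        nonlocal counter
        counter += 1
        pid = f"P{counter:06d}"
        aln_rows.append({"qseqid": pid, "chrom": chrom, "pident":
                         100.0 if mism == 0 else round(100.0 * (plen - mism) / plen, 2),
                         "length": plen, "mismatch": mism,
                         "sstart": start, "send": start + plen,
                         "strand": strand, "hit_count": hits})
        truth_rows.append({"probe_id": pid, "kind": kind, "retained": retained,
                           "true_probeset": region_id if retained else ""})

    for _, reg in annotation.probe_regions.iterrows():
        region_id = f"{reg.true_gene}_{reg.probeset_label}"
        width = reg.end - reg.start
        if width < plen:
            raise ConfigurationError(f"region {region_id} too narrow for probes")
        # clean probes, evenly spread with jitter, always fully inside the exon
        n = config.n_probes_per_probeset
        slots = np.linspace(reg.start, reg.end - plen, n).astype(int)
        jitter = rng.integers(-3, 4, size=n)
        starts = np.clip(slots + jitter, reg.start, reg.end - plen)
        for s in starts:
            add(reg.chrom, reg.strand, int(s), 0, 1, "clean", True, region_id)

    n_clean = counter
    n_bad = int(round(config.frac_problem_probes * n_clean))
    kinds = ["multi_hit", "mismatched", "intergenic", "boundary"]
    regions = annotation.probe_regions
    for b in range(n_bad):
        kind = kinds[b % len(kinds)]
        reg = regions.iloc[int(rng.integers(0, len(regions)))]
        if kind == "multi_hit":
            add(reg.chrom, reg.strand, int(reg.start), 0,
                int(rng.integers(2, 5)), kind, False, "")
        elif kind == "mismatched":
            add(reg.chrom, reg.strand, int(reg.start) + 5,
                int(rng.integers(1, 3)), 1, kind, False, "")
        elif kind == "intergenic":
            # gene pitch leaves a wide gap downstream of the private exon
            add(reg.chrom, reg.strand,
                int(reg.start) + _GENE_PITCH - 800, 0, 1, kind, False, "")
        else:  # boundary: straddle the exon end
            add(reg.chrom, reg.strand, int(reg.end) - plen // 2, 0, 1,
                kind, False, "")
    return pd.DataFrame(aln_rows), pd.DataFrame(truth_rows)


def default_probeset_map(config: SimConfig) -> pd.DataFrame:
    """A standalone probeset->gene map for expression-only simulations.

    Genes receive two probe sets with probability
    ``frac_multi_probeset_genes`` and one otherwise, until ``n_probesets``
    sets exist.  Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    rows = []
    ps = 0
    g = 0
    while ps < config.n_probesets:
        g += 1
        gene = f"SG{g:05d}"
        k = 2 if (rng.random() < config.frac_multi_probeset_genes
                  and ps + 1 < config.n_probesets) else 1
        for j in range(k):
            ps += 1
            rows.append({"probeset_id": f"PS{ps:05d}", "gene_id": gene})
    return pd.DataFrame(rows)


@dataclass
class ExpressionTruth:
    probesets: pd.DataFrame   # probeset_id, gene_id, true_log2fc, is_de, low_signal
    genes: pd.DataFrame       # gene_id, splice_flag


def gen_expression_dataset(
    config: SimConfig,
    probesets: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Simulate the probe-level intensity matrix for the 3/4/5 dpf design.

    log2 intensity = probe-set baseline + per-probe affinity offset + stage
    effect + Normal(0, noise_sd).  The stage effect realizes the true
    5-vs-3 dpf log2 fold change fully at 5 dpf and half at 4 dpf (gradual
    maturation).  Splice-flagged multi-probe-set genes get fold changes of
    +delta and -delta on their two probe sets, so the splicing index is
    exactly +/-delta by construction.  Intensities are exported linear.

    Returns (intensity matrix probes x samples, sample metadata, truth).
    """
    for _stage, n in config.groups:
        if n < 2:
            raise ConfigurationError("each group needs >= 2 replicates")
    rng = _streams(config)["expression"]
    if probesets is None:
        probesets = default_probeset_map(config)
    probesets = probesets.reset_index(drop=True)
    n_ps = len(probesets)

    gene_ps = probesets.groupby("gene_id")["probeset_id"].apply(list)
    multi_genes = sorted(g for g, lst in gene_ps.items() if len(lst) > 1)
    n_splice = int(round(config.frac_splice * len(multi_genes)))
    splice_genes = set(
        np.array(multi_genes)[rng.permutation(len(multi_genes))[:n_splice]]
    ) if multi_genes else set()

    ps_ids = probesets["probeset_id"].to_list()
    gene_of = dict(zip(probesets["probeset_id"], probesets["gene_id"]))
    splice_ps = {p for p in ps_ids if gene_of[p] in splice_genes}

    # low-baseline sets (to be removed by the detection filter) come from
    # non-splice genes; DE is spiked per gene — every probe set of a DE gene
    # shares one fold change, since expression change without splicing moves
    # all of a gene's probe sets together — so each truth label is unambiguous
    pool = [p for p in ps_ids if p not in splice_ps]
    perm = rng.permutation(len(pool))
    n_low = int(round(config.frac_low_signal * n_ps))
    low_ps = {pool[i] for i in perm[:n_low]}
    low_genes = {gene_of[p] for p in low_ps}
    de_gene_pool = sorted({gene_of[p] for p in pool}
                          - low_genes - set(splice_genes))
    de_gene_pool = [de_gene_pool[i]
                    for i in rng.permutation(len(de_gene_pool))]
    n_de = int(round(config.frac_de * n_ps))
    de_ps: set[str] = set()
    de_sign: dict[str, int] = {}
    for gene in de_gene_pool:
        if len(de_ps) >= n_de:
            break
        de_sign[gene] = 1 if rng.random() < 0.5 else -1
        de_ps.update(gene_ps[gene])
    if len(de_ps) < n_de:
        raise ConfigurationError("frac_de too high for the available probe sets")

    true_fc = {}
    for p in ps_ids:
        gene = gene_of[p]
        if p in de_ps:
            true_fc[p] = float(config.log2fc_de * de_sign[gene])
        else:
            true_fc[p] = 0.0
    for gene in sorted(splice_genes):
        members = sorted(gene_ps[gene])
        for j, p in enumerate(members):
            true_fc[p] = config.splice_delta * (1 if j % 2 == 0 else -1)

    lo_b, hi_b = config.baseline_log2_range
    lo_l, hi_l = config.low_baseline_log2_range
    baselines = {
        p: float(rng.uniform(lo_l, hi_l) if p in low_ps else rng.uniform(lo_b, hi_b))
        for p in ps_ids
    }

    samples = []
    for stage, n in config.groups:
        for r in range(1, n + 1):
            samples.append({"sample_id": f"s{stage}_r{r}", "stage": stage,
                            "replicate": r})
    samples_df = pd.DataFrame(samples)
    stage_weight = {stage: w for (stage, _n), w in
                    zip(config.groups, np.linspace(0.0, 1.0, len(config.groups)))}

    probe_ids_of = {}
    if "probes" in probesets.columns:
        for r in probesets.itertuples():
            probes = r.probes.split(";") if isinstance(r.probes, str) else list(r.probes)
            probe_ids_of[r.probeset_id] = sorted(probes)

    probe_rows = []
    values = []
    for p in ps_ids:
        names = probe_ids_of.get(p)
        n_probes = len(names) if names else config.n_probes_per_probeset
        offsets = rng.normal(0.0, 0.8, size=n_probes)
        noise = rng.normal(0.0, config.noise_sd,
                           size=(n_probes, len(samples_df)))
        effects = np.array([stage_weight[s] * true_fc[p]
                            for s in samples_df["stage"]])
        block = baselines[p] + offsets[:, None] + effects[None, :] + noise
        values.append(block)
        probe_rows.extend(names if names
                          else (f"{p}_p{k + 1:02d}" for k in range(n_probes)))
    log2_matrix = np.vstack(values)
    intensities = pd.DataFrame(2.0 ** log2_matrix, index=probe_rows,
                               columns=samples_df["sample_id"].to_list())
    intensities.index.name = "probe_id"

    truth = ExpressionTruth(
        probesets=pd.DataFrame({
            "probeset_id": ps_ids,
            "gene_id": [gene_of[p] for p in ps_ids],
            "true_log2fc": [true_fc[p] for p in ps_ids],
            "is_de": [p in de_ps for p in ps_ids],
            "low_signal": [p in low_ps for p in ps_ids],
        }),
        genes=pd.DataFrame({
            "gene_id": sorted(gene_ps.index),
            "splice_flag": [g in splice_genes for g in sorted(gene_ps.index)],
            "n_probesets": [len(gene_ps[g]) for g in sorted(gene_ps.index)],
        }),
    )
    return intensities, samples_df, truth


@dataclass
class FunctionalTruth:
    spiked_term: str
    homologs: pd.DataFrame   # query_id, subject_id, passes_filter, is_best
    loci: pd.DataFrame       # disease, contains_de_homolog


def gen_functional_annotation(
    config: SimConfig,
    genes: Sequence[str],
    de_genes: set[str],
    id_of: Optional[Mapping[str, str]] = None,
) -> tuple[dict, dict, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, FunctionalTruth]:
    """Emit gene-set catalogs, homolog hits, human coordinates and loci.

    The homolog table includes hits exactly on the 30%-identity / 30%-length
    boundary (kept) and just below it (removed), plus secondary lower-score
    hits to exercise best-hit selection.  One spiked term is populated so
    that ``spiked_pathway_de_fraction`` of its members are DE genes.  Half
    the disease loci are built around DE-gene homolog coordinates
    (candidates exist), half on chromosome regions without them.

    ``id_of`` optionally maps each gene to the identifier written into the
    zebrafish GMT and homolog tables (e.g. a representative transcript id,
    mimicking a blastx of cDNA sequences); defaults to the gene id itself.

    Returns (zebrafish GMT dict, human GMT dict, homolog table,
    human gene BED, loci table, term-category table, truth).
    """
    if config.spiked_pathway_size > len(genes):
        raise ConfigurationError("spiked_pathway_size exceeds number of genes")
    rng = _streams(config)["functional"]
    genes = sorted(genes)
    ident_of = dict(id_of) if id_of is not None else {g: g for g in genes}
    de_sorted = sorted(g for g in de_genes if g in set(genes))
    non_de = [g for g in genes if g not in de_genes]

    # --- homologs -----------------------------------------------------
    n_hom = int(round(config.homolog_coverage * len(genes)))
    hom_genes = sorted(np.array(genes)[rng.permutation(len(genes))[:n_hom]])
    # make sure DE genes are well represented so enrichment/loci have signal
    hom_set = set(hom_genes) | set(de_sorted)
    hom_genes = sorted(hom_set)

    hom_rows, hom_truth = [], []
    for i, g in enumerate(hom_genes):
        subject = f"HS_{g}"
        qlen = int(rng.integers(30, 300)) * 10
        ident = float(np.round(rng.uniform(40.0, 95.0), 1))
        alen = int(rng.uniform(0.5, 1.0) * qlen)
        bits = float(np.round(alen * ident / 50.0, 1))
        hom_rows.append({"query_id": ident_of[g], "subject_id": subject,
                         "pct_identity": ident, "align_length": alen,
                         "query_length": qlen, "bitscore": bits,
                         "evalue": 1e-30})
        hom_truth.append({"query_id": ident_of[g], "subject_id": subject,
                          "passes_filter": True, "is_best": True})
        if i % 4 == 0:  # secondary, lower-scoring hit
            hom_rows.append({"query_id": ident_of[g], "subject_id": f"HS2_{g}",
                             "pct_identity": max(30.0, ident - 10.0),
                             "align_length": max(int(0.3 * qlen), alen - 50),
                             "query_length": qlen, "bitscore": bits / 2.0,
                             "evalue": 1e-10})
            hom_truth.append({"query_id": ident_of[g], "subject_id": f"HS2_{g}",
                              "passes_filter": True, "is_best": False})
    # boundary cases on genes without a clean hit
    no_hom = [g for g in genes if g not in hom_set][:4]
    for j, g in enumerate(no_hom):
        qlen = 500
        if j % 2 == 0:  # exactly on both thresholds -> kept
            hom_rows.append({"query_id": ident_of[g], "subject_id": f"HSB_{g}",
                             "pct_identity": 30.0, "align_length": 150,
                             "query_length": qlen, "bitscore": 60.0,
                             "evalue": 1e-5})
            hom_truth.append({"query_id": ident_of[g], "subject_id": f"HSB_{g}",
                              "passes_filter": True, "is_best": True})
        else:           # just below -> removed
            hom_rows.append({"query_id": ident_of[g], "subject_id": f"HSX_{g}",
                             "pct_identity": 29.9, "align_length": 149,
                             "query_length": qlen, "bitscore": 60.0,
                             "evalue": 1e-5})
            hom_truth.append({"query_id": ident_of[g], "subject_id": f"HSX_{g}",
                              "passes_filter": False, "is_best": False})
    homolog_df = pd.DataFrame(hom_rows)
    ident_to_gene = {v: k for k, v in ident_of.items()}
    subject_of = {ident_to_gene[r["query_id"]]: r["subject_id"] for r in hom_truth
                  if r["passes_filter"] and r["is_best"]}

    # --- gene-set catalogs --------------------------------------------
    namespaces = ["GO_BP", "GO_CC", "GO_MF", "KEGG"]
    zf_gmt: dict[str, tuple[str, list[str]]] = {}
    hu_gmt: dict[str, tuple[str, list[str]]] = {}
    cat_rows = []

    spiked_id = "KEGG:99999"
    de_with_hom = [g for g in de_sorted if g in subject_of]
    n_spiked_de = int(round(config.spiked_pathway_de_fraction
                            * config.spiked_pathway_size))
    n_spiked_de = min(n_spiked_de, len(de_with_hom))
    non_de_with_hom = [g for g in non_de if g in subject_of]
    fill = config.spiked_pathway_size - n_spiked_de
    spiked_members = (de_with_hom[:n_spiked_de] + non_de_with_hom[:fill])
    hu_gmt[spiked_id] = ("KEGG|cytokine signalling cascade",
                         [subject_of[g] for g in spiked_members])
    cat_rows.append({"term_id": spiked_id, "category": "Signal transduction"})

    lo_t, hi_t = config.term_size_range
    gene_arr = np.array(genes)
    for t in range(1, config.n_terms + 1):
        ns = namespaces[t % len(namespaces)]
        size = int(rng.integers(lo_t, hi_t + 1))
        members = sorted(gene_arr[rng.permutation(len(gene_arr))[:size]])
        term_id = f"{ns}:{t:05d}"
        name = f"{ns}|synthetic term {t}"
        if t % 2 == 0:
            zf_gmt[term_id] = (name, [ident_of[m] for m in members])
        else:
            subj = [subject_of[g] for g in members if g in subject_of]
            if subj:
                hu_gmt[term_id] = (name, subj)
        cat_rows.append({"term_id": term_id,
                         "category": GO_CATEGORIES[t % len(GO_CATEGORIES)]})
    categories_df = pd.DataFrame(cat_rows)

    # --- human gene coordinates and disease loci ----------------------
    subjects = sorted({r["subject_id"] for r in hom_rows})
    bed_rows = []
    coords: dict[str, tuple[str, int, int]] = {}
    for i, s in enumerate(subjects):
        chrom = f"chr{(i % 22) + 1}"
        start = 100_000 + (i // 22) * 120_000
        coords[s] = (chrom, start, start + 60_000)
        bed_rows.append({"chrom": chrom, "start": start, "end": start + 60_000,
                         "name": s})
    bed_df = pd.DataFrame(bed_rows)

    de_subjects = [subject_of[g] for g in de_sorted if g in subject_of]
    loci_rows, loci_truth = [], []
    for i in range(config.locus_count):
        disease = f"retinal dystrophy locus {i + 1}"
        omim = f"6{i:05d}"
        if i % 2 == 0 and i // 2 < len(de_subjects):
            chrom, s, e = coords[de_subjects[i // 2]]
            start, end = max(0, s - 500_000), e + 500_000
            hit = True
        else:
            chrom = f"chr{(i % 22) + 1}"
            start, end = 50_000_000 + i * 1_000_000, 52_000_000 + i * 1_000_000
            hit = any(c == chrom and st < end and start < en
                      for c, st, en in (coords[x] for x in de_subjects))
        loci_rows.append({"disease": disease, "omim_id": omim,
                          "chrom": chrom, "start": start, "end": end})
        loci_truth.append({"disease": disease, "contains_de_homolog": hit})
    loci_df = pd.DataFrame(loci_rows)

    truth = FunctionalTruth(
        spiked_term=spiked_id,
        homologs=pd.DataFrame(hom_truth),
        loci=pd.DataFrame(loci_truth),
    )
    return zf_gmt, hu_gmt, homolog_df, bed_df, loci_df, categories_df, truth


@dataclass
class BehaviorTruth:
    larvae: pd.DataFrame   # larva_id, treatment, amplitude
    protocol: dict


def gen_behavior_traces(
    config: SimConfig,
    treatments: Sequence[str] = ("control", "treated"),
) -> tuple[pd.DataFrame, BehaviorTruth]:
    """Simulate per-larva 1 Hz activity traces under the VMR protocol.

    The protocol is ``settle_minutes`` of dark followed by ``light_cycles``
    alternating ON/OFF phases of ``phase_minutes`` each.  Baseline activity
    is Poisson-like at ``baseline_rate`` (or exactly constant when
    ``trace_noise`` is off); at every light transition a burst of known
    realized amplitude (log-normal jitter around ``burst_amplitude``,
    scaled by ``treatment_effect`` in the treated group) is injected with a
    short exponential decay.  The peak bin equals the realized amplitude
    whenever it exceeds baseline, so noiseless traces are exactly
    recoverable.

    Returns a long-format trace table (larva_id, treatment, second,
    activity, light_state) and the truth of injected amplitudes.
    """
    settle = int(round(config.settle_minutes * 60))
    phase = int(round(config.phase_minutes * 60))
    total = settle + 2 * phase * config.light_cycles
    if total <= settle:
        raise ConfigurationError("protocol has no phases after settling")
    rng = _streams(config)["behavior"]

    light = np.empty(total, dtype=object)
    light[:settle] = "OFF"
    for c in range(config.light_cycles):
        on0 = settle + 2 * c * phase
        light[on0:on0 + phase] = "ON"
        light[on0 + phase:on0 + 2 * phase] = "OFF"
    transitions = [(settle + k * phase, "ON" if k % 2 == 0 else "OFF")
                   for k in range(2 * config.light_cycles)]

    decay_len = int(6 * config.burst_decay_s)
    rows = []
    truth_rows = []
    for treatment in treatments:
        scale = 1.0 if treatment == "control" else config.treatment_effect
        for i in range(1, config.n_larvae + 1):
            larva = f"{treatment}_{i:02d}"
            jitter = (math.exp(rng.normal(0.0, config.burst_jitter_sd))
                      if config.burst_jitter_sd > 0 else 1.0)
            amp = config.burst_amplitude * scale * jitter
            if config.trace_noise:
                activity = rng.poisson(config.baseline_rate * 10, size=total) / 10.0
            else:
                activity = np.full(total, config.baseline_rate)
            for t0, _state in transitions:
                for k in range(decay_len):
                    burst = amp * math.exp(-k / config.burst_decay_s)
                    t = t0 + k
                    if t < total:
                        activity[t] = max(activity[t], burst)
            truth_rows.append({"larva_id": larva, "treatment": treatment,
                               "amplitude": amp})
            rows.append(pd.DataFrame({
                "larva_id": larva, "treatment": treatment,
                "second": np.arange(total), "activity": activity,
                "light_state": light,
            }))
    traces = pd.concat(rows, ignore_index=True)
    truth = BehaviorTruth(
        larvae=pd.DataFrame(truth_rows),
        protocol={"settle_s": settle, "phase_s": phase,
                  "n_cycles": config.light_cycles},
    )
    return traces, truth


def traces_to_activity(
    traces: pd.DataFrame, protocol: Mapping[str, int]
):
    """Split a long-format trace table into ActivityTrace objects."""
    from .behavior import ActivityTrace, Protocol

    proto = Protocol(settle_s=int(protocol["settle_s"]),
                     phase_s=int(protocol["phase_s"]),
                     n_cycles=int(protocol["n_cycles"]))
    out = []
    for larva, sub in traces.groupby("larva_id", sort=True):
        sub = sub.sort_values("second")
        out.append(ActivityTrace(
            larva_id=str(larva), treatment=str(sub["treatment"].iloc[0]),
            activity=sub["activity"].to_numpy(),
            light_state=sub["light_state"].to_numpy(), protocol=proto))
    return out


def simulate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full input bundle plus ground-truth tables on disk.

    Writes annotation GFF3s (one per source database), the probe alignment
    table, linear-scale intensities with sample metadata, GMT catalogs,
    homolog hits, human gene BED, disease loci, term categories, behaviour
    traces, and truth TSVs.  Returns a name -> path map.  Byte-identical
    across runs for equal configs.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    truth_dir = outdir / "truth"
    inputs.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann = gen_genome_annotation(config)
    by_source: dict[str, list[TranscriptRecord]] = {}
    for tr in ann.transcripts:
        by_source.setdefault(tr.source_db, []).append(tr)
    for source in sorted(by_source):
        p = inputs / f"annotation_{source}.gff3"
        rio.write_gff3(by_source[source], p)
        paths[f"annotation_{source}"] = p

    aln_df, probe_truth = gen_probe_alignments(config, ann)
    paths["probe_alignments"] = inputs / "probe_alignments.tsv"
    rio.write_tsv(aln_df, paths["probe_alignments"])

    # expression over the annotation-derived truth probe sets, reusing the
    # clean probes' ids so intensities line up with the alignment table
    region_ids = ann.probe_regions.apply(
        lambda r: f"{r.true_gene}_{r.probeset_label}", axis=1)
    clean = probe_truth[probe_truth["retained"]]
    probes_of = clean.groupby("true_probeset")["probe_id"].apply(
        lambda s: ";".join(sorted(s)))
    ps_map = pd.DataFrame({"probeset_id": region_ids,
                           "gene_id": ann.probe_regions["true_gene"],
                           "probes": [probes_of.get(r, "") for r in region_ids]})
    intens, samples_df, expr_truth = gen_expression_dataset(config, ps_map)
    paths["intensities"] = inputs / "intensities.tsv"
    intens.to_csv(paths["intensities"], sep="\t", float_format="%.6f",
                  lineterminator="\n")
    paths["samples"] = inputs / "samples.tsv"
    rio.write_tsv(samples_df, paths["samples"])

    de_genes = set(expr_truth.probesets.loc[expr_truth.probesets["is_de"],
                                            "gene_id"])
    genes = sorted(expr_truth.genes["gene_id"])
    zf_gmt, hu_gmt, hom_df, bed_df, loci_df, cat_df, fn_truth = \
        gen_functional_annotation(
            config, genes, de_genes,
            id_of={g: f"{g}.t1" for g in genes})  # blastx queries are cDNAs
    paths["zebrafish_gmt"] = inputs / "zebrafish_annotation.gmt"
    rio.write_gmt(zf_gmt, paths["zebrafish_gmt"])
    paths["human_gmt"] = inputs / "human_annotation.gmt"
    rio.write_gmt(hu_gmt, paths["human_gmt"])
    paths["homolog_hits"] = inputs / "homolog_hits.tsv"
    rio.write_tsv(hom_df, paths["homolog_hits"])
    paths["human_gene_bed"] = inputs / "human_genes.bed"
    bed_df.to_csv(paths["human_gene_bed"], sep="\t", header=False, index=False,
                  lineterminator="\n")
    paths["loci"] = inputs / "disease_loci.tsv"
    rio.write_tsv(loci_df, paths["loci"])
    paths["term_categories"] = inputs / "term_categories.tsv"
    rio.write_tsv(cat_df, paths["term_categories"])

    traces, beh_truth = gen_behavior_traces(config)
    paths["traces"] = inputs / "traces.csv"
    traces.to_csv(paths["traces"], index=False, float_format="%.4f",
                  lineterminator="\n")

    # ground truth
    paths["truth_transcript_gene"] = truth_dir / "transcript_gene.tsv"
    rio.write_tsv(ann.transcript_gene, paths["truth_transcript_gene"])
    paths["truth_genes"] = truth_dir / "genes.tsv"
    rio.write_tsv(ann.genes, paths["truth_genes"])
    paths["truth_probes"] = truth_dir / "probes.tsv"
    rio.write_tsv(probe_truth, paths["truth_probes"])
    paths["truth_probesets"] = truth_dir / "probesets.tsv"
    rio.write_tsv(expr_truth.probesets, paths["truth_probesets"],
                  float_format="%.4f")
    paths["truth_gene_splice"] = truth_dir / "gene_splice.tsv"
    rio.write_tsv(expr_truth.genes, paths["truth_gene_splice"])
    paths["truth_homologs"] = truth_dir / "homologs.tsv"
    rio.write_tsv(fn_truth.homologs, paths["truth_homologs"])
    paths["truth_loci"] = truth_dir / "loci.tsv"
    rio.write_tsv(fn_truth.loci, paths["truth_loci"])
    paths["truth_spiked_term"] = truth_dir / "spiked_term.tsv"
    rio.write_tsv(pd.DataFrame([{"term_id": fn_truth.spiked_term}]),
                  paths["truth_spiked_term"])
    paths["truth_larvae"] = truth_dir / "larvae.tsv"
    rio.write_tsv(beh_truth.larvae, paths["truth_larvae"], float_format="%.6f")
    paths["truth_protocol"] = truth_dir / "protocol.tsv"
    rio.write_tsv(pd.DataFrame([beh_truth.protocol]), paths["truth_protocol"])
    return paths
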