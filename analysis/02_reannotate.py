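"""Re-annotate the array: transcripts -> genes -> transcript-level probe sets.

Clusters the multi-database transcript models into genes by CDS-exon
overlap, filters probes to perfect unique exonic single-gene hits, groups
the survivors into transcript-level probe sets, and scores the result
against the generator's ground truth.
"""

from pathlib import Path

import pandas as pd

from retinomature import io as rio
from retinomature.reannotate import (ProbeAlignment, build_probe_sets,
                                     cluster_transcripts_to_genes,
                                     filter_probe_alignments)

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main() -> None:
    transcripts = []
    for gff in sorted((STUDY / "inputs").glob("annotation_*.gff3")):
        transcripts.extend(rio.read_gff3_transcripts(gff))
    clusters = cluster_transcripts_to_genes(transcripts)
    print(f"{len(transcripts)} transcripts clustered into {len(clusters)} genes")

    truth = rio.read_tsv(STUDY / "truth" / "transcript_gene.tsv")
    truth_parts = sorted(truth.groupby("true_gene")["transcript_id"]
                         .apply(frozenset), key=sorted)
    ours = sorted((frozenset(c.member_transcript_ids) for c in clusters),
                  key=sorted)
    print(f"  gene partition matches ground truth: {truth_parts == ours}")

    aln = rio.read_tsv(STUDY / "inputs" / "probe_alignments.tsv")
    alignments = [ProbeAlignment(
        probe_id=r.qseqid, chrom=r.chrom, strand=r.strand, start=int(r.sstart),
        length=int(r.send - r.sstart), mismatches=int(r.mismatch),
        hit_count=int(r.hit_count)) for r in aln.itertuples()]
    retained, removed = filter_probe_alignments(alignments, clusters,
                                                transcripts)
    reasons = pd.Series([r for _, r in removed]).value_counts()
    print(f"probes: {len(alignments)} aligned, {len(retained)} retained; "
          f"removed by reason: {reasons.to_dict()}")

    probe_sets, dropped = build_probe_sets(retained, min_probes=3)
    print(f"{len(probe_sets)} transcript-level probe sets over "
          f"{len({ps.gene_id for ps in probe_sets})} genes "
          f"({len(dropped)} under-populated groups dropped)")

    out = pd.DataFrame([{
        "probeset_id": ps.probeset_id, "gene_id": ps.gene_id,
        "n_probes": len(ps.probe_ids),
        "transcripts": ";".join(sorted(ps.covered_transcript_ids)),
        "probes": ";".join(sorted(ps.probe_ids)),
    } for ps in probe_sets])
    rio.write_tsv(out, ROOT / "probe_sets.tsv")
    clusters_df = pd.DataFrame([{
        "gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand,
        "start": c.hull[0], "end": c.hull[1],
        "transcripts": ";".join(sorted(c.member_transcript_ids)),
    } for c in clusters])
    rio.write_tsv(clusters_df, ROOT / "gene_clusters.tsv")
    print(f"wrote {ROOT / 'probe_sets.tsv'} and {ROOT / 'gene_clusters.tsv'}")


if __name__ == "__main__":
    main()
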