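"""Cross-species GO/KEGG enrichment and disease-locus candidates.

Filters homolog hits (>= 30% identity over >= 30% of the query), unions
human annotation onto zebrafish genes through the surviving best hits, runs
one-sided Fisher enrichment of the up- and down-regulated gene sets against
the expressed universe, summarizes DE genes by top-level category, and maps
DE-gene homologs into unsolved retinal-disease loci.
"""

from pathlib import Path

import pandas as pd

from retinomature import io as rio
from retinomature.enrich import (disease_locus_candidates,
                                 fisher_exact_enrichment, go_category_summary,
                                 resolve_loci)
from retinomature.reannotate import (AnnotationCatalog, HomologHit,
                                     combine_annotations, filter_homolog_hits)

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = Path(__file__).resolve().parent.parent / "scratch" / "study"


def to_catalog(gmt):
    cat = AnnotationCatalog()
    for tid, (desc, members) in gmt.items():
        ns, name = desc.split("|", 1) if "|" in desc else ("GO_BP", desc)
        cat.add(tid, name, ns, members)
    return cat


def main() -> None:
    clusters = rio.read_tsv(ROOT / "gene_clusters.tsv")
    tid2gene = {t: r.gene_id for r in clusters.itertuples()
                for t in r.transcripts.split(";")}

    hom = rio.read_tsv(STUDY / "inputs" / "homolog_hits.tsv")
    hits = [HomologHit(query_id=str(r.query_id), subject_id=str(r.subject_id),
                       pct_identity=float(r.pct_identity),
                       align_length=int(r.align_length),
                       query_length=int(r.query_length),
                       bitscore=float(r.bitscore), evalue=float(r.evalue))
            for r in hom.itertuples()]
    best = filter_homolog_hits(hits)
    print(f"homologs: {len(hom)} hits -> {len(best)} queries pass 30%/30% filter")
    best_per_gene = {}
    for q in sorted(best):
        g = tid2gene.get(q, q)
        if g not in best_per_gene or best[q].bitscore > best_per_gene[g].bitscore:
            best_per_gene[g] = best[q]
    hom_map = {g: h.subject_id for g, h in best_per_gene.items()}

    zf = to_catalog(rio.read_gmt(STUDY / "inputs" / "zebrafish_annotation.gmt"))
    for e in zf.terms.values():
        e.gene_ids = {tid2gene.get(g, g) for g in e.gene_ids}
    hu = to_catalog(rio.read_gmt(STUDY / "inputs" / "human_annotation.gmt"))
    catalog, _ = combine_annotations(zf, hu, hom_map)
    print(f"combined catalog: {len(catalog)} terms")

    de = rio.read_tsv(ROOT / "de_table.tsv")
    universe = set(de["gene_id"])
    up = set(de.loc[de["status"] == "up", "gene_id"]) & universe
    down = set(de.loc[de["status"] == "down", "gene_id"]) & universe
    for direction, genes in (("up", up), ("down", down)):
        res = fisher_exact_enrichment(genes, universe, catalog)
        n_sig = int(res["significant"].sum()) if len(res) else 0
        print(f"{direction}: {len(genes)} genes, {len(res)} terms tested, "
              f"{n_sig} significant at q<0.05")
        if n_sig:
            top = res.iloc[0]
            print(f"  top term: {top.term_id} ({top.term_name}), "
                  f"{top.k}/{top.K} genes, q={top.q:.2e}")
        rio.write_tsv(res, ROOT / f"enrichment_{direction}.tsv",
                      float_format="%.6g")

    cats = rio.read_tsv(STUDY / "inputs" / "term_categories.tsv")
    summary = go_category_summary({"up": up, "down": down}, catalog,
                                  dict(cats[["term_id", "category"]]
                                       .itertuples(index=False)))
    rio.write_tsv(summary, ROOT / "category_summary.tsv")

    loci, warn = resolve_loci(rio.read_tsv(STUDY / "inputs" / "disease_loci.tsv"))
    bed = pd.read_csv(STUDY / "inputs" / "human_genes.bed", sep="\t",
                      header=None, names=["chrom", "start", "end", "name"])
    coords = {r.name: (r.chrom, int(r.start), int(r.end))
              for r in bed.itertuples(index=False)}
    cand = disease_locus_candidates(up | down, hom_map, coords, loci)
    print(f"disease mapping: {len(loci)} loci, {len(cand)} candidate "
          f"gene-locus pairs ({cand['disease'].nunique() if len(cand) else 0} "
          f"diseases with candidates)")
    rio.write_tsv(cand, ROOT / "disease_candidates.tsv")


if __name__ == "__main__":
    main()
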