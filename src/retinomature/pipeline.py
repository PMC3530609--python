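"""End-to-end orchestration: re-annotation -> differential expression ->
enrichment (-> behaviour), with a manifest of input hashes and parameters so
a rerun on identical inputs is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as beh
from . import diffexpr as de
from . import enrich as en
from . import io as rio
from . import reannotate as ra
from . import synthgen
from .config import RunConfig

log = logging.getLogger("retinomature")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Optional[Path], stage: str, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(stage, f"missing input: {what} ({path})")
    return Path(path)


def _parse_contrast(contrast: str, stages: list[str]) -> tuple[str, str]:
    """Map a contrast like '5v3' onto the stage labels present."""
    try:
        a, b = contrast.split("v")
    except ValueError:
        raise PipelineError("diffexpr", f"bad contrast {contrast!r}; expected like '5v3'")
    def find(tok: str) -> str:
        for s in stages:
            if tok in s:
                return s
        raise PipelineError("diffexpr", f"no stage matching {tok!r} in {stages}")
    return find(a), find(b)


def _catalog_from_gmt(gmt: dict[str, tuple[str, set[str]]]) -> ra.AnnotationCatalog:
    """GMT descriptions encode the namespace as 'NAMESPACE|term name'."""
    cat = ra.AnnotationCatalog()
    for term_id, (desc, genes) in gmt.items():
        if "|" in desc:
            ns, name = desc.split("|", 1)
        else:
            ns, name = "GO_BP", desc
        cat.add(term_id, name, ns, genes)
    return cat


def infer_protocol(light_state: np.ndarray) -> beh.Protocol:
    """Recover settle/phase/cycle structure from a light-state channel."""
    switches = [t for t in range(1, len(light_state))
                if light_state[t] != light_state[t - 1]]
    if not switches:
        raise PipelineError("behavior", "light channel has no transitions")
    settle = switches[0]
    phase = switches[1] - switches[0] if len(switches) > 1 else len(light_state) - settle
    return beh.Protocol(settle_s=settle, phase_s=phase,
                        n_cycles=max(1, len(switches) // 2))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write artifacts, manifest and report.

    Returns the report dict (stage counts).  Any stage error raises
    ``PipelineError`` naming the stage; the manifest then flags the run
    incomplete.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setLevel(logging.DEBUG)
    log.addHandler(fh)

    manifest: dict = {"parameters": _params_dict(cfg), "complete": False,
                      "inputs": {}, "outputs": {}}
    report: dict = {}
    try:
        # ---- stage 0: simulate -------------------------------------
        if cfg.simulate is not None:
            log.info("simulate: generating synthetic inputs")
            paths = synthgen.simulate_all(cfg.simulate, outdir)
            cfg.annotation_files = sorted(
                p for k, p in paths.items() if k.startswith("annotation_"))
            for attr in ("probe_alignments", "intensities", "samples",
                         "zebrafish_gmt", "human_gmt", "homolog_hits",
                         "human_gene_bed", "loci", "traces", "term_categories"):
                setattr(cfg, attr, paths[attr])

        for p in cfg.annotation_files:
            _require(Path(p), "reannotate", "annotation file")
        manifest["inputs"] = {
            str(p): _sha256(Path(p)) for p in sorted(
                [*map(str, cfg.annotation_files)] + [
                    str(x) for x in (cfg.probe_alignments, cfg.intensities,
                                     cfg.samples, cfg.zebrafish_gmt, cfg.human_gmt,
                                     cfg.homolog_hits, cfg.human_gene_bed,
                                     cfg.loci, cfg.traces, cfg.term_categories)
                    if x is not None and Path(x).exists()])
        }

        # ---- stage 1: reannotate -----------------------------------
        try:
            if not cfg.annotation_files:
                raise ValueError("no annotation files configured")
            transcripts = []
            for p in cfg.annotation_files:
                transcripts.extend(rio.read_gff3_transcripts(p))
            clusters = ra.cluster_transcripts_to_genes(
                transcripts, ignore_strand=cfg.ignore_strand)
            aln_path = _require(cfg.probe_alignments, "reannotate", "probe alignments")
            aln_df = rio.read_tsv(aln_path)
            alignments = [
                ra.ProbeAlignment(
                    probe_id=str(r.qseqid), chrom=str(r.chrom),
                    strand=str(r.strand), start=int(r.sstart),
                    length=int(r.send) - int(r.sstart),
                    mismatches=int(r.mismatch), hit_count=int(r.hit_count))
                for r in aln_df.itertuples()
            ]
            retained, removed = ra.filter_probe_alignments(
                alignments, clusters, transcripts, ignore_strand=cfg.ignore_strand)
            probe_sets, dropped = ra.build_probe_sets(retained, cfg.min_probes)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("reannotate", str(exc)) from exc

        clusters_df = pd.DataFrame([{
            "gene_id": c.gene_id, "chrom": c.chrom, "strand": c.strand,
            "start": c.hull[0], "end": c.hull[1],
            "transcripts": ";".join(sorted(c.member_transcript_ids)),
        } for c in clusters])
        rio.write_tsv(clusters_df, outdir / "gene_clusters.tsv")
        ps_df = pd.DataFrame([{
            "probeset_id": ps.probeset_id, "gene_id": ps.gene_id,
            "n_probes": len(ps.probe_ids),
            "transcripts": ";".join(sorted(ps.covered_transcript_ids)),
            "probes": ";".join(sorted(ps.probe_ids)),
        } for ps in probe_sets])
        rio.write_tsv(ps_df, outdir / "probe_sets.tsv")
        rio.write_tsv(pd.DataFrame(removed, columns=["probe_id", "reason"]),
                      outdir / "probe_removal_log.tsv")
        report.update({
            "n_transcripts": len(transcripts), "n_genes": len(clusters),
            "n_probes_input": len(alignments), "n_probes_retained": len(retained),
            "n_probesets": len(probe_sets),
            "n_probeset_groups_dropped": len(dropped),
            "n_genes_with_probesets": int(ps_df["gene_id"].nunique()) if len(ps_df) else 0,
        })

        # ---- stage 2: diffexpr -------------------------------------
        try:
            intens = rio.read_intensities(
                _require(cfg.intensities, "diffexpr", "intensity matrix"))
            samples = rio.read_tsv(_require(cfg.samples, "diffexpr", "sample metadata"))
            norm = de.quantile_normalize(intens)
            ps_probes = {ps.probeset_id: sorted(ps.probe_ids) for ps in probe_sets}
            # only probes present in the matrix can be summarized
            present = set(norm.index)
            ps_probes = {k: [p for p in v if p in present]
                         for k, v in ps_probes.items()}
            ps_probes = {k: v for k, v in ps_probes.items() if v}
            summarized = de.summarize_probe_sets(norm, ps_probes)
            filtered, removed_rows = de.low_signal_filter(
                summarized, threshold=cfg.signal_floor)
            stages = sorted(samples["stage"].astype(str).unique())
            g1_stage, g2_stage = _parse_contrast(cfg.contrast, stages)
            g1 = samples.loc[samples["stage"].astype(str) == g1_stage,
                             "sample_id"].tolist()
            g2 = samples.loc[samples["stage"].astype(str) == g2_stage,
                             "sample_id"].tolist()
            de_table = de.moderated_t_test(filtered, g1, g2)
            de_table["q"] = de.bh_adjust(de_table["p"].to_numpy())
            de_table = de.select_de(de_table, q_cut=cfg.q_cut,
                                    fc_up=cfg.fc_up, fc_down=cfg.fc_down)
            ps_gene = {ps.probeset_id: ps.gene_id for ps in probe_sets}
            gene_summary, gene_de = de.splicing_index_aggregate(
                de_table, filtered, ps_gene, g1, g2,
                si_gate=cfg.si_gate, q_cut=cfg.q_cut,
                fc_up=cfg.fc_up, fc_down=cfg.fc_down)
            _Z, order, newick, dropped_rows = de.hierarchical_cluster_samples(filtered)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("diffexpr", str(exc)) from exc

        de_out = de_table.copy()
        de_out.insert(0, "probeset_id", de_out.index)
        de_out.insert(1, "gene_id", [ps_gene[i] for i in de_out.index])
        rio.write_tsv(de_out.sort_values(["q", "p", "probeset_id"], kind="stable"),
                      outdir / "de_table.tsv", float_format="%.6g")
        gs_out = gene_summary.reset_index()
        rio.write_tsv(gs_out.sort_values("gene_id"), outdir / "gene_summary.tsv")
        gd_out = gene_de.copy()
        gd_out.insert(0, "gene_id", gd_out.index)
        rio.write_tsv(gd_out.sort_values(["q", "p", "gene_id"], kind="stable"),
                      outdir / "gene_de.tsv", float_format="%.6g")
        (outdir / "sample_dendrogram.nwk").write_text(newick + "\n")
        rio.write_tsv(pd.DataFrame({"probeset_id": removed_rows}),
                      outdir / "low_signal_removed.tsv")
        status_counts = de_table["status"].value_counts()
        report.update({
            "n_probesets_low_signal_removed": len(removed_rows),
            "n_probesets_tested": len(de_table),
            "n_de_up": int(status_counts.get("up", 0)),
            "n_de_down": int(status_counts.get("down", 0)),
            "n_genes_spliced": int(gene_summary["splice_flag"].sum()),
            "n_genes_aggregated": int((~gene_summary["splice_flag"]).sum()),
            "sample_order": ";".join(order),
        })

        # ---- stage 3: enrich ---------------------------------------
        try:
            zf_cat = _catalog_from_gmt(rio.read_gmt(
                _require(cfg.zebrafish_gmt, "enrich", "zebrafish GMT")))
            hu_cat = _catalog_from_gmt(rio.read_gmt(
                _require(cfg.human_gmt, "enrich", "human GMT")))
            hom_df = rio.read_tsv(_require(cfg.homolog_hits, "enrich", "homolog hits"))
            hits = [ra.HomologHit(
                query_id=str(r.query_id), subject_id=str(r.subject_id),
                pct_identity=float(r.pct_identity),
                align_length=int(r.align_length),
                query_length=int(r.query_length),
                bitscore=float(r.bitscore), evalue=float(r.evalue))
                for r in hom_df.itertuples()]
            best = ra.filter_homolog_hits(
                hits, min_identity=cfg.homolog_min_identity,
                min_length_frac=cfg.homolog_min_length_frac)
            # homolog queries and zebrafish-side annotations may be keyed by
            # transcript id (blastx of cDNAs); fold them onto gene clusters
            tid2gene = {tid: c.gene_id for c in clusters
                        for tid in c.member_transcript_ids}
            best_per_gene: dict[str, ra.HomologHit] = {}
            for q in sorted(best):
                gene = tid2gene.get(q, q)
                cur = best_per_gene.get(gene)
                if cur is None or best[q].bitscore > cur.bitscore:
                    best_per_gene[gene] = best[q]
            homolog_map = {g: h.subject_id for g, h in best_per_gene.items()}
            for entry in zf_cat.terms.values():
                entry.gene_ids = {tid2gene.get(g, g) for g in entry.gene_ids}
            universe = set(ps_gene[p] for p in filtered.index if p in ps_gene)
            catalog, _clog = ra.combine_annotations(zf_cat, hu_cat, homolog_map)

            def gene_status(direction: str) -> set[str]:
                agg = set(gene_de.index[gene_de["status"] == direction])
                spliced = set(gene_summary.index[gene_summary["splice_flag"]])
                via_ps = {ps_gene[p] for p in de_table.index
                          if de_table.loc[p, "status"] == direction
                          and ps_gene[p] in spliced}
                return (agg | via_ps) & universe

            up_genes, down_genes = gene_status("up"), gene_status("down")
            enr = {}
            for direction, genes_ in (("up", up_genes), ("down", down_genes)):
                enr[direction] = en.fisher_exact_enrichment(
                    genes_, universe, catalog, q_cut=cfg.q_cut)
                rio.write_tsv(enr[direction], outdir / f"enrichment_{direction}.tsv",
                              float_format="%.6g")
            if cfg.term_categories and Path(cfg.term_categories).exists():
                cat_map = dict(rio.read_tsv(cfg.term_categories)[
                    ["term_id", "category"]].itertuples(index=False))
                summary = en.go_category_summary(
                    {"up": up_genes, "down": down_genes}, catalog, cat_map)
                rio.write_tsv(summary, outdir / "category_summary.tsv")
            loci_list, locus_warnings = [], []
            candidates = pd.DataFrame()
            if cfg.loci and Path(cfg.loci).exists():
                loci_list, locus_warnings = en.resolve_loci(rio.read_tsv(cfg.loci))
                coords = {}
                if cfg.human_gene_bed and Path(cfg.human_gene_bed).exists():
                    bed = pd.read_csv(cfg.human_gene_bed, sep="\t", header=None,
                                      names=["chrom", "start", "end", "name"])
                    coords = {r.name: (r.chrom, int(r.start), int(r.end))
                              for r in bed.itertuples(index=False)}
                candidates = en.disease_locus_candidates(
                    up_genes | down_genes, homolog_map, coords, loci_list)
                rio.write_tsv(candidates, outdir / "disease_candidates.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc

        report.update({
            "n_de_genes_up": len(up_genes), "n_de_genes_down": len(down_genes),
            "n_terms_tested": int(len(enr["up"]) + len(enr["down"])),
            "n_terms_significant_up": int(enr["up"]["significant"].sum()) if len(enr["up"]) else 0,
            "n_terms_significant_down": int(enr["down"]["significant"].sum()) if len(enr["down"]) else 0,
            "n_loci": len(loci_list),
            "n_loci_skipped": len(locus_warnings),
            "n_disease_candidates": len(candidates),
        })

        # ---- stage 4: behavior (optional) --------------------------
        if cfg.traces and Path(cfg.traces).exists():
            try:
                traces = pd.read_csv(cfg.traces)
                first = traces[traces["larva_id"] == traces["larva_id"].iloc[0]]
                proto = infer_protocol(first.sort_values("second")
                                       ["light_state"].to_numpy())
                activity = synthgen.traces_to_activity(
                    traces, {"settle_s": proto.settle_s, "phase_s": proto.phase_s,
                             "n_cycles": proto.n_cycles})
                summaries = [beh.vmr_peaks(tr, peak_window_s=cfg.peak_window_s,
                                           base_window_s=cfg.base_window_s)
                             for tr in activity]
                sdf = beh.summaries_to_frame(summaries)
                rio.write_tsv(sdf.sort_values("larva_id"),
                              outdir / "vmr_summaries.tsv", float_format="%.6g")
                treatments = sorted(sdf["treatment"].unique())
                if len(treatments) >= 2 and "control" in treatments:
                    control = sdf[sdf["treatment"] == "control"]
                    reports = []
                    for t in treatments:
                        if t == "control":
                            continue
                        rep = beh.group_compare(sdf[sdf["treatment"] == t], control)
                        rep.insert(0, "treatment", t)
                        reports.append(rep)
                    vmr_tests = pd.concat(reports, ignore_index=True)
                    rio.write_tsv(vmr_tests, outdir / "vmr_tests.tsv",
                                  float_format="%.6g")
                    report["vmr_min_p"] = float(vmr_tests["p"].min())
                report["n_larvae"] = int(sdf["larva_id"].nunique())
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("behavior", str(exc)) from exc

        manifest["complete"] = True
    finally:
        for name in sorted(p.name for p in outdir.iterdir()
                           if p.is_file() and p.name not in
                           ("manifest.json", "run.log")):
            manifest["outputs"][name] = _sha256(outdir / name)
        manifest["report"] = report
        with open(outdir / "manifest.json", "w") as fhj:
            json.dump(manifest, fhj, indent=2, sort_keys=True)
        _write_report(report, outdir / "run_report.txt")
        log.removeHandler(fh)
        fh.close()
    return report


def _params_dict(cfg: RunConfig) -> dict:
    out = {}
    for k, v in vars(cfg).items():
        if k == "simulate":
            out[k] = None if v is None else {kk: _jsonable(vv)
                                             for kk, vv in vars(v).items()}
        else:
            out[k] = _jsonable(v)
    return out


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def _write_report(report: dict, path: Path) -> None:
    lines = ["retinomature run report", "=" * 23]
    for k in sorted(report):
        lines.append(f"{k}: {report[k]}")
    path.write_text("\n".join(lines) + "\n")
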