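"""Transcript clustering, probe filtering, probe-set construction and
homolog filtering."""

import pytest
from hypothesis import given, settings, strategies as st

from retinomature.reannotate import (
    HomologHit, ProbeAlignment, TranscriptRecord,
    AnnotationCatalog, brute_force_cluster, build_probe_sets,
    cluster_transcripts_to_genes, combine_annotations,
    filter_homolog_hits, filter_probe_alignments,
)
from conftest import make_transcript


class TestTranscriptClustering:
    def test_chained_overlap_merges_transitively(self):
        # T1-T2 overlap on [150,200), T2-T3 on [240,250); T4 is antisense
        t1 = make_transcript("T1", exons=[(100, 200)])
        t2 = make_transcript("T2", exons=[(150, 250)])
        t3 = make_transcript("T3", exons=[(240, 300)])
        t4 = make_transcript("T4", strand="-", exons=[(100, 200)])
        clusters = cluster_transcripts_to_genes([t1, t2, t3, t4])
        parts = sorted(sorted(c.member_transcript_ids) for c in clusters)
        assert parts == [["T1", "T2", "T3"], ["T4"]]

    def test_singleton_and_cross_chromosome(self):
        t1 = make_transcript("T1", chrom="chr1")
        t5 = make_transcript("T5", chrom="chr2")
        clusters = cluster_transcripts_to_genes([t1, t5])
        assert len(clusters) == 2
        assert cluster_transcripts_to_genes([t1])[0].member_transcript_ids == {"T1"}

    def test_duplicate_ids_rejected(self):
        t = make_transcript("T1")
        with pytest.raises(ValueError, match="duplicate"):
            cluster_transcripts_to_genes([t, make_transcript("T1", chrom="chr9")])

    def test_empty_input_gives_empty_output(self):
        assert cluster_transcripts_to_genes([]) == []

    def test_ignore_strand_merges_antisense(self):
        t1 = make_transcript("T1", strand="+")
        t2 = make_transcript("T2", strand="-")
        assert len(cluster_transcripts_to_genes([t1, t2])) == 2
        merged = cluster_transcripts_to_genes([t1, t2], ignore_strand=True)
        assert len(merged) == 1

    def test_partition_property(self):
        ts = [make_transcript(f"T{i}", exons=[(i * 50, i * 50 + 80)])
              for i in range(20)]
        clusters = cluster_transcripts_to_genes(ts)
        members = [tid for c in clusters for tid in c.member_transcript_ids]
        assert sorted(members) == sorted(t.transcript_id for t in ts)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(1, 30))
        ts = []
        for i in range(n):
            chrom = data.draw(st.sampled_from(["chr1", "chr2"]))
            strand = data.draw(st.sampled_from(["+", "-"]))
            n_ex = data.draw(st.integers(1, 3))
            exons, pos = [], 0
            for _ in range(n_ex):
                start = pos + data.draw(st.integers(0, 120))
                end = start + data.draw(st.integers(1, 100))
                exons.append((start, end))
                pos = end
            ts.append(make_transcript(f"T{i}", chrom=chrom, strand=strand,
                                      exons=exons))
        fast = sorted((frozenset(c.member_transcript_ids)
                       for c in cluster_transcripts_to_genes(ts)), key=sorted)
        assert fast == brute_force_cluster(ts)

    def test_permutation_invariance(self):
        ts = [make_transcript(f"T{i}", exons=[(i * 30, i * 30 + 50)])
              for i in range(12)]
        a = cluster_transcripts_to_genes(ts)
        b = cluster_transcripts_to_genes(list(reversed(ts)))
        assert [(c.gene_id, sorted(c.member_transcript_ids)) for c in a] == \
               [(c.gene_id, sorted(c.member_transcript_ids)) for c in b]


class TestProbeFiltering:
    @pytest.fixture
    def setup(self):
        t1 = make_transcript("T1", exons=[(1000, 1500)])
        t2 = make_transcript("T2", exons=[(1200, 1700)])
        ts = [t1, t2]
        clusters = cluster_transcripts_to_genes(ts)
        return ts, clusters

    def make_aln(self, pid, start, mism=0, hits=1, chrom="chr1", strand="+"):
        return ProbeAlignment(probe_id=pid, chrom=chrom, strand=strand,
                              start=start, length=25, mismatches=mism,
                              hit_count=hits)

    def test_filter_rules(self, setup):
        ts, clusters = setup
        alns = [
            self.make_aln("clean", 1100),          # inside T1 only
            self.make_aln("both", 1300),           # inside T1 and T2
            self.make_aln("multihit", 1100, hits=2),
            self.make_aln("mismatch", 1100, mism=1),
            self.make_aln("boundary", 1490),       # straddles T1 end, in T2
            self.make_aln("intergenic", 5000),
        ]
        retained, removed = filter_probe_alignments(alns, clusters, ts)
        assert set(retained) == {"clean", "both", "boundary"}
        assert retained["clean"].covered_transcript_ids == {"T1"}
        assert retained["both"].covered_transcript_ids == {"T1", "T2"}
        # boundary probe is fully inside T2's exon even though it crosses T1's
        assert retained["boundary"].covered_transcript_ids == {"T2"}
        reasons = dict(removed)
        assert reasons == {"multihit": "multi_hit", "mismatch": "mismatched",
                           "intergenic": "not_exonic"}

    def test_exon_boundary_partial_overlap_removed(self):
        ts = [make_transcript("T1", exons=[(1000, 1500)])]
        clusters = cluster_transcripts_to_genes(ts)
        retained, removed = filter_probe_alignments(
            [self.make_aln("edge", 1490)], clusters, ts)
        assert not retained and removed == [("edge", "not_exonic")]

    def test_unknown_chromosome_errors(self, setup):
        ts, clusters = setup
        with pytest.raises(ValueError, match="unknown chromosome"):
            filter_probe_alignments([self.make_aln("p", 10, chrom="chrZ")],
                                    clusters, ts)


class TestProbeSets:
    def _assign(self, pid, tset, gene="G00001"):
        from retinomature.reannotate import ProbeAssignment
        return ProbeAssignment(probe_id=pid,
                               covered_transcript_ids=frozenset(tset),
                               gene_id=gene)

    def test_exact_transcript_set_grouping(self):
        assigns = {f"p{i}": self._assign(f"p{i}", {"T1", "T2"}) for i in range(11)}
        assigns.update({f"q{i}": self._assign(f"q{i}", {"T1"}) for i in range(4)})
        sets, dropped = build_probe_sets(assigns, min_probes=3)
        assert len(sets) == 2 and not dropped
        sizes = sorted(len(ps.probe_ids) for ps in sets)
        assert sizes == [4, 11]

    def test_min_probes_threshold(self):
        assigns = {f"p{i}": self._assign(f"p{i}", {"T1"}) for i in range(2)}
        sets, dropped = build_probe_sets(assigns, min_probes=3)
        assert not sets and dropped == [("G00001_PS1", 2)]
        with pytest.raises(ValueError):
            build_probe_sets(assigns, min_probes=0)

    def test_monotone_in_min_probes(self):
        assigns = {}
        for g, n in (("GA", 2), ("GB", 5), ("GC", 11)):
            for i in range(n):
                assigns[f"{g}p{i}"] = self._assign(f"{g}p{i}", {g + "T"}, gene=g)
        counts = [len(build_probe_sets(assigns, min_probes=k)[0])
                  for k in range(1, 13)]
        assert counts == sorted(counts, reverse=True)


class TestHomologFilter:
    def hit(self, q="g1", s="h1", ident=50.0, alen=200, qlen=400,
            bits=100.0, ev=1e-20):
        return HomologHit(query_id=q, subject_id=s, pct_identity=ident,
                          align_length=alen, query_length=qlen,
                          bitscore=bits, evalue=ev)

    def test_inclusive_boundaries(self):
        # exactly 30% identity over exactly 30% of the query is kept
        kept = filter_homolog_hits([self.hit(ident=30.0, alen=120, qlen=400)])
        assert "g1" in kept
        assert not filter_homolog_hits([self.hit(ident=29.9)])
        assert not filter_homolog_hits([self.hit(alen=119, qlen=400)])

    def test_highest_bitscore_wins(self):
        hits = [self.hit(s="hA", bits=120.0), self.hit(s="hB", bits=180.0)]
        assert filter_homolog_hits(hits)["g1"].subject_id == "hB"

    def test_tie_breaks_on_evalue_then_subject(self):
        hits = [self.hit(s="hB", bits=100.0, ev=1e-10),
                self.hit(s="hA", bits=100.0, ev=1e-20)]
        assert filter_homolog_hits(hits)["g1"].subject_id == "hA"
        hits = [self.hit(s="hB"), self.hit(s="hA")]
        assert filter_homolog_hits(hits)["g1"].subject_id == "hA"

    def test_one_subject_per_query(self):
        hits = [self.hit(q=f"g{i % 3}", s=f"h{i}") for i in range(9)]
        best = filter_homolog_hits(hits)
        assert set(best) == {"g0", "g1", "g2"}

    def test_invalid_query_length_rejected(self):
        with pytest.raises(ValueError):
            self.hit(qlen=0)


class TestCombineAnnotations:
    def _cats(self):
        zf = AnnotationCatalog()
        zf.add("GO:1", "vision", "GO_BP", {"g1"})
        hu = AnnotationCatalog()
        hu.add("GO:1", "visual perception", "GO_BP", {"h2"})
        hu.add("KEGG:9", "jak-stat signalling", "KEGG", {"h2", "h3"})
        return zf, hu

    def test_homolog_transfer_union(self):
        zf, hu = self._cats()
        combined, log = combine_annotations(zf, hu, {"g2": "h2"})
        assert combined.genes_for("GO:1") == {"g1", "g2"}
        assert combined.genes_for("KEGG:9") == {"g2"}
        # human metadata wins on the shared term, and the override is logged
        assert combined.terms["GO:1"].name == "visual perception"
        assert any("overrides" in line for line in log)

    def test_gene_without_homolog_unchanged(self):
        zf, hu = self._cats()
        combined, _ = combine_annotations(zf, hu, {})
        assert combined.genes_for("GO:1") == {"g1"}

    def test_double_annotation_deduplicated(self):
        zf, hu = self._cats()
        zf.add("KEGG:9", "jak-stat signalling", "KEGG", {"g2"})
        combined, _ = combine_annotations(zf, hu, {"g2": "h2"})
        assert combined.genes_for("KEGG:9") == {"g2"}

    def test_unknown_gene_skipped_with_warning(self):
        zf, hu = self._cats()
        combined, log = combine_annotations(zf, hu, {"gX": "h2"},
                                            known_genes={"g1"})
        assert all("gX" not in e.gene_ids for e in combined.terms.values())
        assert any("unknown gene" in line for line in log)
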