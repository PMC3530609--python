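"""Custom genome re-annotation and probe remapping.

The Affymetrix zebrafish array was designed against an early genome build, so
its vendor probe sets mix probes from distinct genes and miss transcripts
added later.  This module rebuilds the annotation layer from scratch:

1. transcripts from several source databases are clustered into genes by
   overlap of their coding (CDS) exons — two transcripts belong to the same
   gene iff they are connected, directly or transitively, by at least 1 bp of
   CDS overlap on the same chromosome and strand;
2. individual 25-mer probes are filtered to perfect, genome-unique, fully
   exonic, single-gene hits;
3. surviving probes are regrouped into transcript-level probe sets — probes
   covering exactly the same set of transcripts within a gene form one set;
4. zebrafish genes are linked to human proteins through a best-hit homolog
   filter (>= 30% identity over >= 30% of the query length), which lets human
   GO/KEGG annotation be transferred onto zebrafish genes.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

VALID_SOURCES = {"ensembl", "genbank", "zfin", "refseq", "synthetic"}


class Namespace(str, Enum):
    GO_BP = "GO_BP"
    GO_CC = "GO_CC"
    GO_MF = "GO_MF"
    KEGG = "KEGG"


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript model: an ordered set of CDS exons on one strand."""

    transcript_id: str
    source_db: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.cds_exons:
            raise ValueError(f"{self.transcript_id}: at least one CDS exon required")
        prev_end = -1
        for start, end in self.cds_exons:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]


@dataclass(frozen=True)
class GeneCluster:
    """A connected component of CDS-overlapping transcripts."""

    gene_id: str
    chrom: str
    strand: str
    member_transcript_ids: frozenset[str]
    hull: tuple[int, int]


@dataclass(frozen=True)
class ProbeAlignment:
    """One genomic hit of a 25-mer probe, BLAST-tabular style."""

    probe_id: str
    chrom: str
    strand: str
    start: int
    length: int
    mismatches: int
    hit_count: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.probe_id}: length must be > 0")
        if self.hit_count < 1:
            raise ValueError(f"{self.probe_id}: hit_count must be >= 1")
        if self.mismatches < 0:
            raise ValueError(f"{self.probe_id}: mismatches must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class ProbeAssignment:
    """A retained probe and the transcripts whose CDS exons contain it."""

    probe_id: str
    covered_transcript_ids: frozenset[str]
    gene_id: str


@dataclass(frozen=True)
class ProbeSet:
    probeset_id: str
    probe_ids: frozenset[str]
    covered_transcript_ids: frozenset[str]
    gene_id: str


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    query_length: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"{self.query_id}: pct_identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")
        if self.query_length <= 0:
            raise ValueError(f"{self.query_id}: query_length must be > 0")


@dataclass
class TermEntry:
    name: str
    namespace: Namespace
    gene_ids: set[str] = field(default_factory=set)


@dataclass
class AnnotationCatalog:
    """term_id -> (name, namespace, annotated gene set)."""

    terms: dict[str, TermEntry] = field(default_factory=dict)

    def add(self, term_id: str, name: str, namespace: Namespace | str,
            gene_ids: Iterable[str]) -> None:
        ns = Namespace(namespace)
        entry = self.terms.setdefault(term_id, TermEntry(name, ns))
        entry.gene_ids.update(gene_ids)

    def genes_for(self, term_id: str) -> set[str]:
        return self.terms[term_id].gene_ids

    def __len__(self) -> int:
        return len(self.terms)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_transcripts_to_genes(
    transcripts: Sequence[TranscriptRecord],
    *,
    ignore_strand: bool = False,
) -> list[GeneCluster]:
    """Cluster transcripts into genes by connected CDS-exon overlap.

    Two transcripts share a gene iff they are linked (directly or through
    intermediates) by >= 1 bp of CDS overlap on the same chromosome and, by
    default, the same strand — antisense models are treated as distinct
    genes unless ``ignore_strand`` is set.

    Runs a sweep line over exon intervals with union-find: within each
    (chrom, strand) group exons are sorted by start, and any exon starting
    before the running maximum end is unioned with the component owning that
    maximum.  Gene ids are assigned deterministically after sorting clusters
    by (chrom, hull start, smallest member transcript id).
    """
    seen: set[str] = set()
    for tr in transcripts:
        if tr.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id {tr.transcript_id!r}")
        seen.add(tr.transcript_id)
    if not transcripts:
        return []

    uf = _UnionFind(tr.transcript_id for tr in transcripts)
    groups: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for tr in transcripts:
        key = (tr.chrom, "." if ignore_strand else tr.strand)
        for start, end in tr.cds_exons:
            groups[key].append((start, end, tr.transcript_id))

    for exons in groups.values():
        exons.sort()
        run_end = -1
        run_rep: Optional[str] = None
        for start, end, tid in exons:
            if run_rep is not None and start < run_end:
                uf.union(run_rep, tid)
                run_end = max(run_end, end)
            else:
                run_rep, run_end = tid, end

    by_tid = {tr.transcript_id: tr for tr in transcripts}
    components: dict[str, list[str]] = defaultdict(list)
    for tid in sorted(by_tid):
        components[uf.find(tid)].append(tid)

    raw = []
    for members in components.values():
        first = by_tid[members[0]]
        starts = [by_tid[m].span[0] for m in members]
        ends = [by_tid[m].span[1] for m in members]
        strand = "." if ignore_strand else first.strand
        raw.append((first.chrom, min(starts), min(members), strand,
                    max(ends), members))
    raw.sort()
    width = max(5, len(str(len(raw))))
    return [
        GeneCluster(
            gene_id=f"G{i + 1:0{width}d}",
            chrom=chrom, strand=strand,
            member_transcript_ids=frozenset(members),
            hull=(start, end),
        )
        for i, (chrom, start, _mid, strand, end, members) in enumerate(raw)
    ]


def brute_force_cluster(
    transcripts: Sequence[TranscriptRecord], *, ignore_strand: bool = False
) -> list[frozenset[str]]:
    """O(n^2) all-pairs overlap + connected components; the reference oracle.

    Returns the partition as a sorted list of member-id sets (no gene ids),
    so results are comparable across implementations.
    """
    def overlaps(a: TranscriptRecord, b: TranscriptRecord) -> bool:
        if a.chrom != b.chrom:
            return False
        if not ignore_strand and a.strand != b.strand:
            return False
        return any(s1 < e2 and s2 < e1
                   for s1, e1 in a.cds_exons for s2, e2 in b.cds_exons)

    uf = _UnionFind(tr.transcript_id for tr in transcripts)
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1:]:
            if overlaps(a, b):
                uf.union(a.transcript_id, b.transcript_id)
    comps: dict[str, set[str]] = defaultdict(set)
    for tr in transcripts:
        comps[uf.find(tr.transcript_id)].add(tr.transcript_id)
    return sorted((frozenset(v) for v in comps.values()), key=sorted)


def filter_probe_alignments(
    alignments: Sequence[ProbeAlignment],
    clusters: Sequence[GeneCluster],
    transcripts: Sequence[TranscriptRecord],
    *,
    ignore_strand: bool = False,
) -> tuple[dict[str, ProbeAssignment], list[tuple[str, str]]]:
    """Retain clean probes and map each to the transcripts containing it.

    A probe survives iff it aligns with zero mismatches, hits the genome
    exactly once, lies entirely within a CDS exon, and every transcript whose
    exon contains it belongs to one gene cluster.  Returns the retained
    probe -> assignment map and a removal log of (probe_id, reason).
    """
    known_chroms = {tr.chrom for tr in transcripts}
    gene_of = {tid: cl.gene_id
               for cl in clusters for tid in cl.member_transcript_ids}

    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for tr in transcripts:
        strand = "." if ignore_strand else tr.strand
        for start, end in tr.cds_exons:
            trees[(tr.chrom, strand)].addi(start, end, tr.transcript_id)

    retained: dict[str, ProbeAssignment] = {}
    removed: list[tuple[str, str]] = []
    for aln in alignments:
        if aln.chrom not in known_chroms:
            raise ValueError(
                f"probe {aln.probe_id} aligned to unknown chromosome {aln.chrom!r}")
        if aln.mismatches > 0:
            removed.append((aln.probe_id, "mismatched"))
            continue
        if aln.hit_count > 1:
            removed.append((aln.probe_id, "multi_hit"))
            continue
        strand = "." if ignore_strand else aln.strand
        covered = {
            iv.data
            for iv in trees[(aln.chrom, strand)].overlap(aln.start, aln.end)
            if iv.begin <= aln.start and aln.end <= iv.end  # entirely within
        }
        if not covered:
            removed.append((aln.probe_id, "not_exonic"))
            continue
        genes = {gene_of[tid] for tid in covered}
        if len(genes) != 1:
            removed.append((aln.probe_id, "multi_gene"))
            continue
        retained[aln.probe_id] = ProbeAssignment(
            probe_id=aln.probe_id,
            covered_transcript_ids=frozenset(covered),
            gene_id=genes.pop(),
        )
    return retained, removed


def build_probe_sets(
    assignments: Mapping[str, ProbeAssignment],
    min_probes: int = 3,
) -> tuple[list[ProbeSet], list[tuple[str, int]]]:
    """Group retained probes into transcript-level probe sets.

    Within a gene, probes covering exactly the same transcript set form one
    probe set; a gene with probes discriminating among its transcripts
    therefore owns several sets.  Groups below ``min_probes`` are dropped and
    reported as (would-be probeset id, probe count).
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    groups: dict[tuple[str, tuple[str, ...]], list[str]] = defaultdict(list)
    for pid in sorted(assignments):
        a = assignments[pid]
        groups[(a.gene_id, tuple(sorted(a.covered_transcript_ids)))].append(pid)

    probe_sets: list[ProbeSet] = []
    dropped: list[tuple[str, int]] = []
    by_gene: dict[str, list[tuple[tuple[str, ...], list[str]]]] = defaultdict(list)
    for (gene_id, tset), pids in groups.items():
        by_gene[gene_id].append((tset, pids))
    for gene_id in sorted(by_gene):
        for k, (tset, pids) in enumerate(sorted(by_gene[gene_id]), start=1):
            ps_id = f"{gene_id}_PS{k}"
            if len(pids) < min_probes:
                dropped.append((ps_id, len(pids)))
                continue
            probe_sets.append(ProbeSet(
                probeset_id=ps_id,
                probe_ids=frozenset(pids),
                covered_transcript_ids=frozenset(tset),
                gene_id=gene_id,
            ))
    return probe_sets, dropped


def filter_homolog_hits(
    hits: Sequence[HomologHit],
    *,
    min_identity: float = 30.0,
    min_length_frac: float = 0.30,
) -> dict[str, HomologHit]:
    """Best human homolog per query under the 30%/30% filter.

    A hit survives with identity >= ``min_identity`` percent and an aligned
    length covering >= ``min_length_frac`` of the query (both bounds
    inclusive).  Among survivors the highest bitscore wins; ties break by
    lowest e-value, then lexicographic subject id.  Queries with no
    surviving hit are absent from the result.
    """
    best: dict[str, HomologHit] = {}
    for hit in hits:
        if hit.pct_identity < min_identity:
            continue
        if hit.align_length < min_length_frac * hit.query_length - 1e-9:
            continue
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key = (-hit.bitscore, hit.evalue, hit.subject_id)
        cur_key = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key < cur_key:
            best[hit.query_id] = hit
    return best


def combine_annotations(
    zebrafish_catalog: AnnotationCatalog,
    human_catalog: AnnotationCatalog,
    homolog_map: Mapping[str, str],
    *,
    known_genes: Optional[set[str]] = None,
) -> tuple[AnnotationCatalog, list[str]]:
    """Union zebrafish annotation with terms transferred through homologs.

    A zebrafish gene gains every term its best human homolog is annotated
    to.  Term metadata comes from whichever catalog defines the term; the
    human name wins when both define it (logged).  Homolog-map entries for
    genes outside ``known_genes`` (when given) are skipped with a warning
    string in the returned log.
    """
    out = AnnotationCatalog()
    log: list[str] = []
    for term_id in sorted(zebrafish_catalog.terms):
        e = zebrafish_catalog.terms[term_id]
        out.add(term_id, e.name, e.namespace, e.gene_ids)

    subject_terms: dict[str, list[str]] = defaultdict(list)
    for term_id in sorted(human_catalog.terms):
        e = human_catalog.terms[term_id]
        if term_id in out.terms and out.terms[term_id].name != e.name:
            log.append(f"term {term_id}: human name {e.name!r} overrides "
                       f"zebrafish name {out.terms[term_id].name!r}")
        if term_id in out.terms:
            out.terms[term_id].name = e.name
        else:
            out.add(term_id, e.name, e.namespace, [])
        for subj in e.gene_ids:
            subject_terms[subj].append(term_id)

    for gene in sorted(homolog_map):
        if known_genes is not None and gene not in known_genes:
            log.append(f"homolog map references unknown gene {gene!r}; skipped")
            continue
        for term_id in subject_terms.get(homolog_map[gene], ()):
            out.terms[term_id].gene_ids.add(gene)

    # terms that end up with no annotated genes carry no information
    for term_id in [t for t, e in out.terms.items() if not e.gene_ids]:
        del out.terms[term_id]
    return out, log
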