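"""Gene-set enrichment and disease-locus candidate mapping.

Enrichment is the classical one-sided Fisher exact (hypergeometric
upper-tail) test of a differentially expressed gene list against term gene
sets from the combined zebrafish + transferred-human GO/KEGG catalog, with
BH adjustment within each namespace and significance called at q < 0.05.
Disease-locus mapping intersects the human homolog coordinates of DE genes
with intervals of mapped-but-unsolved inherited retinal disease loci, the
candidate-gene step of the original screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .diffexpr import bh_adjust
from .reannotate import AnnotationCatalog


@dataclass(frozen=True)
class DiseaseLocus:
    """A human genomic interval linked to an inherited retinal disease."""

    disease_name: str
    omim_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"{self.disease_name}: start must be < end")


def fisher_exact_enrichment(
    de_genes: set[str],
    universe: set[str],
    catalog: AnnotationCatalog,
    *,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``de_genes`` over the catalog.

    Per term with K = |term ∩ universe| > 0 and k = |term ∩ de_genes|, the
    p-value is the hypergeometric upper tail P(X >= k) drawing n = |de|
    genes from a universe of N.  BH runs within each namespace; rows are
    sorted by (q, p, term_id) and flagged significant at q < ``q_cut``.
    """
    extra = de_genes - universe
    if extra:
        raise ValueError(f"DE genes outside the universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(de_genes)
    rows = []
    for term_id in sorted(catalog.terms):
        entry = catalog.terms[term_id]
        members = entry.gene_ids & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term_id, "term_name": entry.name,
            "namespace": entry.namespace.value,
            "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                     "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = np.nan
        for ns, idx in df.groupby("namespace").groups.items():
            df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
        df["significant"] = df["q"] < q_cut
        df = df.sort_values(["q", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Direct summation of the hypergeometric mass for P(X >= k); test oracle."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def go_category_summary(
    de_genes_by_direction: Mapping[str, set[str]],
    catalog: AnnotationCatalog,
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Count DE genes per top-level category, up and down separately.

    ``category_map`` maps term_id to a display category (e.g. the custom
    summary categories Adhesion ... Vision and light stimulus).  A gene is
    counted once per category regardless of how many of the category's
    terms annotate it; genes annotated by no categorized term fall under
    ``other``.
    """
    categories = sorted(set(category_map.values())) + ["other"]
    rows = []
    for direction in sorted(de_genes_by_direction):
        genes = de_genes_by_direction[direction]
        per_cat: dict[str, set[str]] = {c: set() for c in categories}
        categorized: set[str] = set()
        for term_id, entry in catalog.terms.items():
            cat = category_map.get(term_id)
            if cat is None:
                continue
            hit = entry.gene_ids & genes
            per_cat[cat] |= hit
            categorized |= hit
        per_cat["other"] = genes - categorized
        for cat in categories:
            rows.append({"direction": direction, "category": cat,
                         "n_genes": len(per_cat[cat])})
    return pd.DataFrame(rows)


_BAND_RE = re.compile(r"^(?P<chrom>[0-9XY]{1,2})(?P<arm>[pq])(?P<band>[\d.]+)?$")


def resolve_cytoband_range(
    location: str, band_table: pd.DataFrame
) -> tuple[str, int, int]:
    """Resolve a cytogenetic location like ``6q14-q16.2`` to coordinates.

    ``band_table`` is UCSC cytoBand format: chrom, start, end, band name
    (e.g. q14.1), stain.  A range resolves to (start of first matching band,
    end of last matching band); a bare arm or band prefix matches every
    sub-band it prefixes.
    """
    loc = location.strip().replace(" ", "")
    parts = loc.split("-")
    m = _BAND_RE.match(parts[0])
    if m is None:
        raise ValueError(f"unparseable cytogenetic location {location!r}")
    chrom = f"chr{m.group('chrom')}"
    first = m.group("arm") + (m.group("band") or "")
    if len(parts) == 1:
        last = first
    else:
        tail = parts[1]
        m2 = _BAND_RE.match(tail)
        if m2 and _BAND_RE.match(tail).group("chrom"):
            # allow fully-qualified second endpoint like 6q16.2
            last = m2.group("arm") + (m2.group("band") or "")
        else:
            last = tail  # e.g. "q16.2"

    sub = band_table[band_table["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"chromosome {chrom} absent from band table")

    def match(prefix: str) -> pd.DataFrame:
        names = sub["band"].astype(str)
        exact = sub[(names == prefix) | names.str.startswith(prefix + ".")]
        if exact.empty and not prefix[-1].isdigit():
            exact = sub[names.str.startswith(prefix)]
        return exact

    b1, b2 = match(first), match(last)
    if b1.empty or b2.empty:
        raise ValueError(f"band(s) {first!r}/{last!r} not found on {chrom}")
    start = int(min(b1["start"].min(), b2["start"].min()))
    end = int(max(b1["end"].max(), b2["end"].max()))
    return chrom, start, end


def resolve_loci(
    loci_table: pd.DataFrame,
    band_table: Optional[pd.DataFrame] = None,
) -> tuple[list[DiseaseLocus], list[str]]:
    """Build DiseaseLocus records from a loci table.

    Rows with explicit ``chrom``/``start``/``end`` are taken as-is; rows
    with a ``location`` cytoband string instead are resolved through
    ``band_table``.  Unresolvable rows are skipped with a warning string.
    """
    out: list[DiseaseLocus] = []
    warnings: list[str] = []
    for _, row in loci_table.iterrows():
        try:
            if "location" in row and isinstance(row.get("location"), str) and row["location"]:
                if band_table is None:
                    raise ValueError("cytoband location given but no band table")
                chrom, start, end = resolve_cytoband_range(row["location"], band_table)
            else:
                chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
            out.append(DiseaseLocus(
                disease_name=str(row["disease"]), omim_id=str(row["omim_id"]),
                chrom=chrom, start=start, end=end))
        except (ValueError, KeyError) as exc:
            warnings.append(f"locus {row.get('disease', '?')!r} skipped: {exc}")
    return out, warnings


def disease_locus_candidates(
    de_genes: set[str],
    homolog_map: Mapping[str, str],
    human_gene_coords: Mapping[str, tuple[str, int, int]],
    loci: Sequence[DiseaseLocus],
) -> pd.DataFrame:
    """List DE genes whose human homolog falls inside a disease locus.

    A gene is a candidate for a locus when its homolog's interval overlaps
    the locus interval by >= 1 bp on the same chromosome.  Output is ordered
    by disease then gene, and is invariant to input order.
    """
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        trees.setdefault(locus.chrom, IntervalTree()).addi(
            locus.start, locus.end, locus)

    rows = []
    for gene in sorted(de_genes):
        subject = homolog_map.get(gene)
        if subject is None or subject not in human_gene_coords:
            continue
        chrom, start, end = human_gene_coords[subject]
        for iv in trees.get(chrom, IntervalTree()).overlap(start, end):
            locus: DiseaseLocus = iv.data
            rows.append({
                "disease": locus.disease_name, "omim_id": locus.omim_id,
                "locus": f"{locus.chrom}:{locus.start}-{locus.end}",
                "gene_id": gene, "human_homolog": subject,
                "homolog_interval": f"{chrom}:{start}-{end}",
            })
    df = pd.DataFrame(rows, columns=["disease", "omim_id", "locus", "gene_id",
                                     "human_homolog", "homolog_interval"])
    return df.sort_values(["disease", "gene_id"], kind="stable").reset_index(drop=True)
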