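"""TSS classification (gTSS/iTSS/aTSS/nTSS), 5'-UTR statistics and census.

Category rules, strand-aware in 1-based coordinates:

* gTSS -- same strand as a protein-coding gene, 1..``gtss_window`` nt
  upstream of its start codon (window end inclusive). With the optional
  coverage extension, a TSS any distance upstream also qualifies when the
  pooled RNA-seq coverage is at least ``coverage_floor`` at every base
  between the TSS and the start codon; this is how 5'-UTRs longer than
  the window can exist.
* iTSS -- same strand, inside any annotated gene body.
* aTSS -- opposite strand, inside a gene body extended by ``atss_flank``
  nt on both sides.
* nTSS -- up to ``gtss_window`` nt upstream (same strand) of an
  ncRNA-class feature, or no other rule fires (intergenic).

Every firing rule is kept in ``all_categories``; the single reported
category is the highest-precedence member (default
gTSS > iTSS > aTSS > nTSS, since gene-leading promoters carry the
5'-UTR and differential-activity analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from .end_coverage import EndCountTrack
from .genome_model import GeneFeature, GenomeAnnotation, NCRNA_CLASSES
from .tss_detection import TSSCall

CATEGORIES = ("gTSS", "iTSS", "aTSS", "nTSS")


@dataclass
class ClassificationConfig:
    gtss_window: int = 200
    atss_flank: int = 50
    leaderless_max: int = 10
    long_utr_min: int = 200
    precedence: tuple = ("gTSS", "iTSS", "aTSS", "nTSS")
    use_coverage_extension: bool = False
    coverage_floor: int = 5

    def __post_init__(self) -> None:
        if min(self.gtss_window, self.atss_flank) < 0:
            raise ValueError("windows must be >= 0")
        if sorted(self.precedence) != sorted(CATEGORIES):
            raise ValueError("precedence must permute the four categories")


@dataclass
class TSSRecord:
    replicon: str
    position: int
    strand: str
    active_conditions: set[str]
    tag_counts: dict[str, int]
    category: str
    associated_gene_id: Optional[str]
    utr_length: Optional[int]      # gTSS only
    leaderless: bool
    all_categories: set[str]

    @property
    def tss_id(self) -> str:
        return f"{self.replicon}:{self.position}:{self.strand}"


class _GeneIndex:
    """Interval lookups over gene bodies and aTSS envelopes."""

    def __init__(self, annotation: GenomeAnnotation, atss_flank: int):
        self.body: dict[str, IntervalTree] = {}
        self.envelope: dict[str, IntervalTree] = {}
        for g in annotation.genes:
            self.body.setdefault(g.replicon_id, IntervalTree()).addi(
                g.start, g.end + 1, g
            )
            self.envelope.setdefault(g.replicon_id, IntervalTree()).addi(
                max(1, g.start - atss_flank), g.end + atss_flank + 1, g
            )
        self.by_replicon: dict[str, list[GeneFeature]] = {}
        for g in annotation.genes:
            self.by_replicon.setdefault(g.replicon_id, []).append(g)

    def genes_containing(self, replicon: str, pos: int) -> list[GeneFeature]:
        tree = self.body.get(replicon)
        return [iv.data for iv in tree[pos]] if tree else []

    def genes_enveloping(self, replicon: str, pos: int) -> list[GeneFeature]:
        tree = self.envelope.get(replicon)
        return [iv.data for iv in tree[pos]] if tree else []


def _upstream_distance(tss: int, strand: str, gene: GeneFeature) -> int:
    """Strand-aware distance from the TSS to the gene's 5' start (>0 = upstream)."""
    return gene.start - tss if strand == "+" else tss - gene.end


def _coverage_continuous(
    track: EndCountTrack, replicon: str, strand: str, lo: int, hi: int, floor: int
) -> bool:
    posmap = track.positions(replicon, strand)
    return all(posmap.get(p, 0) >= floor for p in range(lo, hi + 1))


def classify_tss(
    tss_call: TSSCall,
    annotation: GenomeAnnotation,
    config: ClassificationConfig | None = None,
    rnaseq_track: EndCountTrack | None = None,
    _index: _GeneIndex | None = None,
) -> TSSRecord:
    """Assign categories to one TSS call and pick the winning one.

    The associated gene is the nearest gene satisfying the winning rule
    (ties broken toward the smaller start coordinate).
    """
    config = config or ClassificationConfig()
    idx = _index or _GeneIndex(annotation, config.atss_flank)
    pos, strand, replicon = tss_call.position, tss_call.strand, tss_call.replicon

    fired: dict[str, list[tuple[int, GeneFeature]]] = {c: [] for c in CATEGORIES}

    # gTSS: windowed (or coverage-extended) upstream of a same-strand CDS
    same_strand_cds = [
        g
        for g in idx.by_replicon.get(replicon, [])
        if g.strand == strand and g.is_coding
    ]
    nearest_downstream: Optional[GeneFeature] = None
    nearest_d = None
    for g in same_strand_cds:
        d = _upstream_distance(pos, strand, g)
        if 1 <= d <= config.gtss_window:
            fired["gTSS"].append((d, g))
        if d >= 1 and (nearest_d is None or d < nearest_d):
            nearest_downstream, nearest_d = g, d
    if (
        config.use_coverage_extension
        and rnaseq_track is not None
        and not fired["gTSS"]
        and nearest_downstream is not None
    ):
        # only the nearest downstream CDS can pass: the coverage span to any
        # farther start contains this one's span
        g = nearest_downstream
        lo, hi = (pos, g.start - 1) if strand == "+" else (g.end + 1, pos)
        if _coverage_continuous(
            rnaseq_track, replicon, strand, lo, hi, config.coverage_floor
        ):
            fired["gTSS"].append((nearest_d, g))

    # iTSS / aTSS: gene-body containment (any feature class)
    for g in idx.genes_containing(replicon, pos):
        if g.strand == strand:
            d = min(abs(pos - g.start), abs(pos - g.end))
            fired["iTSS"].append((d, g))
    for g in idx.genes_enveloping(replicon, pos):
        if g.strand != strand:
            d = min(abs(pos - g.start), abs(pos - g.end))
            fired["aTSS"].append((d, g))

    # nTSS: upstream of an ncRNA-class feature, same strand
    for g in idx.by_replicon.get(replicon, []):
        if g.strand == strand and g.feature_class in NCRNA_CLASSES:
            d = _upstream_distance(pos, strand, g)
            if 1 <= d <= config.gtss_window:
                fired["nTSS"].append((d, g))

    all_categories = {c for c in CATEGORIES if fired[c]}
    if not all_categories:
        all_categories = {"nTSS"}

    category = next(c for c in config.precedence if c in all_categories)
    gene_id = None
    utr_length = None
    if fired[category]:
        d, gene = min(fired[category], key=lambda t: (t[0], t[1].start))
        gene_id = gene.gene_id
        if category == "gTSS":
            utr_length = d
    leaderless = utr_length is not None and utr_length <= config.leaderless_max
    return TSSRecord(
        replicon=replicon,
        position=pos,
        strand=strand,
        active_conditions=set(tss_call.active_conditions),
        tag_counts=dict(tss_call.tag_counts),
        category=category,
        associated_gene_id=gene_id,
        utr_length=utr_length,
        leaderless=leaderless,
        all_categories=all_categories,
    )


def classify_all(
    tss_calls: list[TSSCall],
    annotation: GenomeAnnotation,
    config: ClassificationConfig | None = None,
    rnaseq_track: EndCountTrack | None = None,
) -> list[TSSRecord]:
    config = config or ClassificationConfig()
    idx = _GeneIndex(annotation, config.atss_flank)
    return [
        classify_tss(c, annotation, config, rnaseq_track, _index=idx)
        for c in tss_calls
    ]


def compute_utr_statistics(
    records: list[TSSRecord], config: ClassificationConfig | None = None
) -> dict:
    """5'-UTR summary over gTSS records.

    leaderless: UTR length <= ``leaderless_max`` nt;
    long: UTR length > ``long_utr_min`` nt.
    """
    config = config or ClassificationConfig()
    lengths = sorted(
        r.utr_length for r in records if r.category == "gTSS" and r.utr_length is not None
    )
    if not lengths:
        warnings.warn("no gTSS records: empty 5'-UTR summary")
        return {
            "n_gtss": 0,
            "median_utr": None,
            "leaderless": 0,
            "long_utr": 0,
            "histogram": ([], []),
        }
    arr = np.asarray(lengths)
    hist, edges = np.histogram(arr, bins=range(0, int(arr.max()) + 26, 25))
    return {
        "n_gtss": len(lengths),
        "median_utr": float(np.median(arr)),
        "leaderless": int(np.sum(arr <= config.leaderless_max)),
        "long_utr": int(np.sum(arr > config.long_utr_min)),
        "histogram": (hist.tolist(), edges.tolist()),
    }


def census_from_counts(category_counts: dict[str, int]) -> dict:
    """Census arithmetic for one replicon/condition cell.

    Returns the total plus, per category, (count, percentage of the
    total rounded to 2 decimals). An all-zero cell reports blank
    percentages.
    """
    total = sum(category_counts.get(c, 0) for c in CATEGORIES)
    rows = {}
    for c in CATEGORIES:
        n = category_counts.get(c, 0)
        pct = round(100.0 * n / total, 2) if total > 0 else None
        rows[c] = (n, pct)
    return {"total": total, "categories": rows}


def summarize_tss_counts(records: list[TSSRecord]) -> dict:
    """Table-style census: per replicon x {union, per-condition} category counts.

    For each replicon and for each activity subset (the union plus every
    condition seen), reports the per-category count and its percentage of
    that cell's total, and grand totals across replicons.
    """
    replicons = sorted({r.replicon for r in records})
    conditions = sorted({c for r in records for c in r.active_conditions})
    subsets = ["union"] + conditions
    table: dict[str, dict[str, dict]] = {}
    for rep in replicons:
        table[rep] = {}
        rep_records = [r for r in records if r.replicon == rep]
        for subset in subsets:
            if subset == "union":
                chosen = rep_records
            else:
                chosen = [r for r in rep_records if subset in r.active_conditions]
            counts = {c: sum(1 for r in chosen if r.category == c) for c in CATEGORIES}
            table[rep][subset] = census_from_counts(counts)
    grand = {}
    for subset in subsets:
        counts = {
            c: sum(table[rep][subset]["categories"][c][0] for rep in replicons)
            for c in CATEGORIES
        }
        grand[subset] = census_from_counts(counts)
    return {"per_replicon": table, "grand_total": grand}
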