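"""Comparative genomics: conserved-protein flags and flexible genomic islands.

Flexible genomic islands (fGIs) are called from a pairwise whole-genome
alignment hit table (BLAST outfmt-6 dialect): long, high-identity hits
("anchors") are chained collinearly along the query, and every maximal
anchor-free query interval of at least ``min_island_length`` bp (default
10 kb, the synteny-break rule) is an island. Collinearity is enforced by
a length-weighted longest-increasing-subsequence chain over subject
coordinates, so off-diagonal repeats do not rescue synteny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome_model import GenomeAnnotation

BLAST6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "e_value",
    "bit_score",
]


@dataclass
class FgiConfig:
    min_island_length: int = 10_000
    anchor_min_length: int = 1_000
    anchor_min_identity: float = 70.0
    collinear: bool = True

    def __post_init__(self) -> None:
        if self.min_island_length <= 0:
            raise ValueError("min_island_length must be > 0")


@dataclass
class ConservationThresholds:
    max_evalue: float = 1e-5
    min_query_coverage: float = 80.0  # strict >
    min_identity: float = 30.0        # strict >


@dataclass
class FlexibleIsland:
    replicon: str
    start: int   # 1-based inclusive
    end: int
    genes: list[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_blast_table(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file (optional 13th qcovs column)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = BLAST6_COLUMNS + ["query_coverage"]
    elif df.shape[1] == 12:
        df.columns = BLAST6_COLUMNS
    else:
        raise ValueError(f"{path}: expected 12 or 13 columns, found {df.shape[1]}")
    return df


def filter_conserved_hits(
    hits: pd.DataFrame,
    thresholds: ConservationThresholds | None = None,
    query_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Flag each query gene conserved/flexible from its best hit.

    Conserved requires, on the best hit (lowest e-value, then highest bit
    score): e-value < max_evalue, query coverage > min_query_coverage and
    identity > min_identity -- all strict. Queries with no hit are
    flexible. Coverage is taken from a ``query_coverage`` column or, if
    absent, computed from the alignment span and ``query_lengths``.
    """
    thresholds = thresholds or ConservationThresholds()
    df = hits.copy()
    if "query_coverage" not in df.columns:
        if query_lengths is None:
            raise ValueError(
                "hit table has no query_coverage column; supply query_lengths"
            )
        span = (df["query_end"] - df["query_start"]).abs() + 1
        df["query_coverage"] = 100.0 * span / df["query_id"].map(query_lengths)
    if (df["query_coverage"] > 100 + 1e-9).any():
        bad = df.loc[df["query_coverage"] > 100 + 1e-9, "query_id"].iloc[0]
        raise ValueError(f"query {bad}: coverage > 100%")
    order = df.sort_values(["e_value", "bit_score"], ascending=[True, False])
    best = order.groupby("query_id", sort=True).first().reset_index()
    best["conserved"] = (
        (best["e_value"] < thresholds.max_evalue)
        & (best["query_coverage"] > thresholds.min_query_coverage)
        & (best["percent_identity"] > thresholds.min_identity)
    )
    return best[["query_id", "e_value", "query_coverage", "percent_identity", "conserved"]]


def _weighted_lis(values: Sequence[float], weights: Sequence[float]) -> list[int]:
    """Indices of the max-weight strictly increasing subsequence (O(n^2))."""
    n = len(values)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if n == 0:
        return []
    i = max(range(n), key=lambda k: best[k])
    chain = []
    while i != -1:
        chain.append(i)
        i = prev[i]
    return chain[::-1]


def call_flexible_islands(
    hits: pd.DataFrame,
    query_genome_length: int,
    config: FgiConfig | None = None,
    annotation: Optional[GenomeAnnotation] = None,
    replicon_id: str = "chromosome",
) -> list[FlexibleIsland]:
    """Call fGIs on one query replicon against one reference genome.

    Anchors are hits with alignment length >= anchor_min_length and
    identity >= anchor_min_identity, chained collinearly (best of the
    forward and reverse subject orientations). Islands are the maximal
    anchor-free query intervals >= min_island_length, clipped to
    [1, genome length]; genes are listed when an annotation is given.
    """
    config = config or FgiConfig()
    anchors = hits[
        (hits["alignment_length"] >= config.anchor_min_length)
        & (hits["percent_identity"] >= config.anchor_min_identity)
    ].copy()
    intervals: list[tuple[int, int]] = []
    if len(anchors):
        a_start = anchors[["query_start", "query_end"]].min(axis=1)
        a_end = anchors[["query_start", "query_end"]].max(axis=1)
        s_mid = (anchors["subject_start"] + anchors["subject_end"]) / 2.0
        order = a_start.argsort(kind="stable").to_numpy()
        qs = a_start.to_numpy()[order]
        qe = a_end.to_numpy()[order]
        sm = s_mid.to_numpy()[order]
        w = anchors["alignment_length"].to_numpy(dtype=float)[order]
        if config.collinear and len(qs) > 1:
            fwd = _weighted_lis(sm, w)
            rev = _weighted_lis([-v for v in sm], w)
            chain = fwd if sum(w[i] for i in fwd) >= sum(w[i] for i in rev) else rev
        else:
            chain = list(range(len(qs)))
        intervals = sorted((int(qs[i]), int(qe[i])) for i in chain)

    # merge anchor intervals, then walk the gaps
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    islands: list[FlexibleIsland] = []

    def maybe_add(lo: int, hi: int) -> None:
        lo, hi = max(1, lo), min(query_genome_length, hi)
        if hi - lo + 1 >= config.min_island_length:
            genes = []
            if annotation is not None:
                genes = [
                    g.gene_id
                    for g in annotation.genes_on(replicon_id)
                    if g.start <= hi and g.end >= lo
                ]
            islands.append(FlexibleIsland(replicon_id, lo, hi, genes))

    cursor = 1
    for s, e in merged:
        maybe_add(cursor, s - 1)
        cursor = e + 1
    maybe_add(cursor, query_genome_length)
    return islands


def write_islands_bed(islands: list[FlexibleIsland], path) -> None:
    """BED (0-based half-open) output of called islands."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands, start=1):
            fh.write(f"{isl.replicon}\t{isl.start - 1}\t{isl.end}\tfGI_{i}\n")
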