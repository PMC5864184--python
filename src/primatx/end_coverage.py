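"""Strand-specific read-5'-end count tracks.

dRNA-seq TSS calling consumes *5'-end* counts: each read contributes one
count at the genomic position of its 5' terminus, not full coverage.
Tracks are stored sparsely per (replicon, strand) as position -> count in
the package's 1-based frame; on disk they are 4-column bedGraph
(0-based, half-open), one file per strand because bedGraph has no strand
column (suffix convention: ``.plus`` / ``.minus``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

TREATMENTS = ("TEX", "MINUS", "RNASEQ")


@dataclass(frozen=True)
class LibraryMeta:
    """Identity of one sequencing library.

    condition: experimental condition label, "A" or "B" (in the motivating
    study: 37 ppt and 43 ppt salinity). treatment: TEX (5'PPP-enriched
    dRNA-seq), MINUS (processed-end background from the same sample), or
    RNASEQ (pooled classic coverage library).
    """

    library_id: str
    condition: str
    replicate: int
    treatment: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class EndCountTrack:
    """Per-(replicon, strand) sparse map position -> 5'-end count."""

    meta: LibraryMeta
    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def get(self, replicon: str, strand: str, position: int) -> int:
        return self.counts.get((replicon, strand), {}).get(position, 0)

    def add(self, replicon: str, strand: str, position: int, count: int) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        if count == 0:
            return
        d = self.counts.setdefault((replicon, strand), {})
        d[position] = d.get(position, 0) + count

    def positions(self, replicon: str, strand: str) -> dict[int, int]:
        return self.counts.get((replicon, strand), {})


def _read_bedgraph_into(track: EndCountTrack, path, strand: str) -> None:
    intervals: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start_s, end_s, value_s = fields
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if value < 0:
                raise ValueError(f"{path}: line {lineno}: negative value {value}")
            if value != int(value):
                raise ValueError(f"{path}: line {lineno}: non-integer count {value}")
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: empty interval")
            intervals.append((chrom, start, end, int(value)))
    intervals.sort()
    prev_chrom, prev_end = None, -1
    for chrom, start, end, value in intervals:
        if chrom == prev_chrom and start < prev_end:
            raise ValueError(
                f"{path}: interval {chrom}:{start}-{end} overlaps a previous "
                f"interval (ambiguous counts)"
            )
        prev_chrom, prev_end = chrom, end
        if value == 0:
            continue
        # 0-based half-open [start, end) -> 1-based positions start+1..end
        d = track.counts.setdefault((chrom, strand), {})
        for pos in range(start + 1, end + 1):
            d[pos] = value


def read_end_count_track(path_plus, path_minus_strand, meta: LibraryMeta) -> EndCountTrack:
    """Read one library's plus- and minus-strand bedGraph files.

    Intervals are expanded to per-position counts; zero-valued intervals
    are dropped. Overlapping intervals within one strand are an error.
    """
    track = EndCountTrack(meta=meta)
    _read_bedgraph_into(track, path_plus, "+")
    _read_bedgraph_into(track, path_minus_strand, "-")
    return track


def write_end_count_track(track: EndCountTrack, path_plus, path_minus_strand) -> None:
    """Write a track to a bedGraph pair, merging runs of equal counts."""
    for strand, path in (("+", path_plus), ("-", path_minus_strand)):
        with open(path, "w") as fh:
            for (chrom, s), posmap in sorted(track.counts.items()):
                if s != strand:
                    continue
                run_start = run_val = prev = None
                for pos in sorted(posmap):
                    val = posmap[pos]
                    if run_start is not None and pos == prev + 1 and val == run_val:
                        prev = pos
                        continue
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start - 1}\t{prev}\t{run_val}\n")
                    run_start = prev = pos
                    run_val = val
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start - 1}\t{prev}\t{run_val}\n")


def scale_to_common_depth(tracks: list[EndCountTrack]) -> dict[str, float]:
    """Per-library depth scale factors: geometric-mean total / library total.

    Multiplying a library's counts by its factor equalises effective
    sequencing depth across libraries, so the product factor_i * total_i
    is constant.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to scale")
    totals = {}
    for t in tracks:
        tot = t.total_count
        if tot == 0:
            raise ValueError(f"library {t.meta.library_id} has total count 0")
        totals[t.meta.library_id] = tot
    log_gm = sum(math.log(v) for v in totals.values()) / len(totals)
    gm = math.exp(log_gm)
    return {lib: gm / tot for lib, tot in totals.items()}


def track_from_bam(bam_path, meta: LibraryMeta) -> EndCountTrack:
    """Build a 5'-end track from a coordinate-indexed BAM/SAM (optional utility).

    Primary alignments only; the 5' end is the leftmost aligned base for
    +-strand reads and the rightmost for --strand reads. Requires pysam.
    """
    import pysam

    track = EndCountTrack(meta=meta)
    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(bam_path), mode) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_reverse:
                track.add(read.reference_name, "-", read.reference_end, 1)
            else:
                track.add(read.reference_name, "+", read.reference_start + 1, 1)
    return track
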