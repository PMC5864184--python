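"""Sequence motif scanning over 5'-UTRs and promoter regions.

Two scanners:

* CsrA/Rsm binding-site scan. CsrA recognises A(N)GGA motifs; a
  candidate target 5'-UTR is one whose suffix matches
  ``GGA[ACGT]{4,70}GGA[ACGT]{2,12}$`` -- two GGA cores, 4-70 nt apart,
  the second one 2-12 nt before the end of the UTR (i.e. close to the
  start codon, where bound CsrA occludes the ribosome-binding site).
  The anchor is the end of the supplied sequence; an optional
  ``cds_extension`` lets callers append the first bases of the CDS
  before scanning.
* A generic IUPAC motif scanner with mismatches, both strands, with
  positions reported relative to the sequence end so that promoter
  windows ending at TSS-1 give TSS-anchored offsets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

CSRA_PATTERN = re.compile(r"GGA[ACGT]{4,70}GGA[ACGT]{2,12}$")
_ANGGA = re.compile(r"(?=A[ACGT]GGA)")
_VALID_SEQ = re.compile(r"^[ACGT]*$")

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class CsrAScanConfig:
    spacer1_min: int = 4
    spacer1_max: int = 70
    tail_min: int = 2
    tail_max: int = 12
    cds_extension: int = 0  # nt of CDS appended to the UTR before scanning


@dataclass
class CsrAHit:
    seq_id: str
    match_start: int        # 0-based within the scanned sequence
    match_end: int          # exclusive; equals len(sequence) (end-anchored)
    spacer1: int            # nt between the two GGA cores
    tail: int               # nt after the second GGA to the sequence end
    n_angga: int            # additional A(N)GGA occurrences in the sequence
    spacer_combinations: list[tuple[int, int]] = field(default_factory=list)


def _pattern_for(config: CsrAScanConfig) -> re.Pattern:
    return re.compile(
        f"GGA[ACGT]{{{config.spacer1_min},{config.spacer1_max}}}"
        f"GGA[ACGT]{{{config.tail_min},{config.tail_max}}}$"
    )


def scan_csra_sites(
    sequences: dict[str, str], config: CsrAScanConfig | None = None
) -> list[CsrAHit]:
    """Scan 5'-UTR sequences for end-anchored CsrA-binding sites.

    One hit per matching sequence (leftmost match, greedy-longest first
    spacer); all valid (spacer1, tail) combinations are enumerated as
    diagnostics. Sequences with non-ACGT characters are skipped with a
    warning.
    """
    config = config or CsrAScanConfig()
    pattern = _pattern_for(config)
    hits = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        if not seq:
            continue
        if not _VALID_SEQ.match(seq):
            warnings.warn(f"{seq_id}: non-ACGT characters, sequence skipped")
            continue
        m = pattern.search(seq)
        if m is None:
            continue
        combos = _enumerate_spacers(seq, config)
        # decompose the reported match: first GGA at m.start(), greedy
        # (longest) first spacer as the regex engine matches it
        start = m.start()
        spacer1, tail = _decompose(seq, start, config)
        hits.append(
            CsrAHit(
                seq_id=seq_id,
                match_start=start,
                match_end=len(seq),
                spacer1=spacer1,
                tail=tail,
                n_angga=len(_ANGGA.findall(seq)),
                spacer_combinations=combos,
            )
        )
    return hits


def _second_ok(seq: str, start: int, spacer: int) -> bool:
    j = start + 3 + spacer
    return seq[j : j + 3] == "GGA"


def _decompose(seq: str, start: int, config: CsrAScanConfig) -> tuple[int, int]:
    """Greedy-longest spacer1 consistent with the match start."""
    best = None
    for spacer in range(config.spacer1_max, config.spacer1_min - 1, -1):
        j = start + 3 + spacer
        tail = len(seq) - (j + 3)
        if tail < config.tail_min or tail > config.tail_max:
            continue
        if _second_ok(seq, start, spacer):
            best = (spacer, tail)
            break
    if best is None:  # cannot happen for a regex match
        raise AssertionError("regex match without a valid decomposition")
    return best


def _enumerate_spacers(seq: str, config: CsrAScanConfig) -> list[tuple[int, int]]:
    combos = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "GGA":
            continue
        for j in range(i + 3, n - 2):
            if seq[j : j + 3] != "GGA":
                continue
            spacer = j - (i + 3)
            tail = n - (j + 3)
            if (
                config.spacer1_min <= spacer <= config.spacer1_max
                and config.tail_min <= tail <= config.tail_max
            ):
                combos.append((spacer, tail))
    return combos


@dataclass
class IupacMatch:
    seq_id: str
    start: int            # 0-based within the sequence
    end_offset: int       # start - len(sequence); TSS-anchored when the
                          # sequence is a promoter window ending at TSS-1
    strand: str           # + = as given, - = motif on the reverse complement
    mismatches: int
    matched: str


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


def scan_iupac_motif(
    sequences: dict[str, str],
    iupac_pattern: str,
    max_mismatches: int = 0,
) -> list[IupacMatch]:
    """All windows matching an IUPAC pattern with <= max_mismatches, both strands."""
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    pattern = iupac_pattern.upper()
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern")
    patterns = {"+": pattern, "-": reverse_complement_iupac(pattern)}
    k = len(pattern)
    out = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        for strand, pat in patterns.items():
            sets = [IUPAC[c] for c in pat]
            for start in range(0, len(seq) - k + 1):
                window = seq[start : start + k]
                mm = sum(1 for c, allowed in zip(window, sets) if c not in allowed)
                if mm <= max_mismatches:
                    out.append(
                        IupacMatch(
                            seq_id=seq_id,
                            start=start,
                            end_offset=start - len(seq),
                            strand=strand,
                            mismatches=mm,
                            matched=window,
                        )
                    )
    return out


def load_csra_target_hits(path) -> list[dict]:
    """Ingest tabular output of an external CsrA target predictor (hook).

    Expects a TSV with a header line naming at least ``gene_id``; all
    columns are passed through untouched. The external algorithm itself
    is not reimplemented here.
    """
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = list(reader)
    if rows and "gene_id" not in rows[0]:
        raise ValueError("external CsrA target table must have a gene_id column")
    return rows
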