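"""Genome sequence + annotation model.

Everything downstream (TSS classification, 5'-UTR extraction, promoter
windows) is expressed in the coordinate frame defined here: 1-based,
inclusive, GFF3-style. The TSS position is the first transcribed
nucleotide. For a minus-strand gene the biological "gene start" (the
5'-most transcribed base) is the feature's *end* coordinate; all window
arithmetic in this package is strand-aware in that sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

#: GFF3 feature types mapped onto the feature classes the TSS rules use.
#: CDS-class genes are eligible gTSS targets; the ncRNA classes make a TSS
#: upstream of them an nTSS.
_FEATURE_CLASS_BY_TYPE = {
    "CDS": "CDS",
    "gene": "CDS",  # plain gene rows default to protein-coding
    "protein_coding_gene": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "sRNA": "sRNA",
    "ncRNA": "other_ncRNA",
    "tmRNA": "other_ncRNA",
    "RNase_P_RNA": "other_ncRNA",
    "SRP_RNA": "other_ncRNA",
    "antisense_RNA": "other_ncRNA",
}

NCRNA_CLASSES = frozenset({"tRNA", "rRNA", "sRNA", "other_ncRNA"})


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene feature in 1-based inclusive coordinates."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"{self.start}..{self.end} (1-based inclusive, start<=end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most transcribed base (gene start)."""
        return self.start if self.strand == "+" else self.end

    @property
    def is_coding(self) -> bool:
        return self.feature_class == "CDS"


@dataclass
class Replicon:
    id: str
    length: int
    sequence: str


@dataclass
class GenomeAnnotation:
    """Replicons plus typed gene features; the coordinate frame for the pipeline."""

    replicons: list[Replicon]
    genes: list[GeneFeature]
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for rep in self.replicons:
            if rep.id in self._by_id:
                raise ValueError(f"duplicate replicon id {rep.id!r}")
            self._by_id[rep.id] = rep
        for g in self.genes:
            rep = self._by_id.get(g.replicon_id)
            if rep is None:
                raise ValueError(
                    f"gene {g.gene_id} references unknown replicon {g.replicon_id!r}"
                )
            if g.end > rep.length:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds replicon "
                    f"{rep.id} length {rep.length}"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        try:
            return self._by_id[replicon_id]
        except KeyError:
            raise KeyError(f"unknown replicon {replicon_id!r}") from None

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene {gene_id!r}")

    def genes_on(self, replicon_id: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.replicon_id == replicon_id]


def _parse_gff3_attributes(attr_field: str) -> dict:
    attrs = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_genome_annotation(fasta_path, gff3_path) -> GenomeAnnotation:
    """Parse a genome FASTA plus GFF3 annotation into a GenomeAnnotation.

    Sequences are upper-cased. One GeneFeature is produced per annotated
    gene; the feature class (CDS vs the ncRNA classes) is inferred from
    the GFF3 ``type`` column. Unknown seqids and malformed coordinates
    are hard errors (the latter with the offending line number).
    """
    replicons = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        replicons.append(Replicon(id=rec.id, length=len(seq), sequence=seq))
    known_ids = {r.id for r in replicons}

    genes: list[GeneFeature] = []
    seen_ids: set[str] = set()
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr = fields
            if ftype not in _FEATURE_CLASS_BY_TYPE:
                continue
            if seqid not in known_ids:
                raise ValueError(
                    f"{gff3_path}: line {lineno}: seqid {seqid!r} not present "
                    f"in the FASTA"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{gff3_path}: line {lineno}: malformed coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from None
            attrs = _parse_gff3_attributes(attr)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"feature_{lineno}"
            if gene_id in seen_ids:
                # a gene row followed by its CDS child shares the locus; keep
                # the first (the CDS/exact-typed row wins via type priority below)
                continue
            seen_ids.add(gene_id)
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_class=_FEATURE_CLASS_BY_TYPE[ftype],
                )
            )
    return GenomeAnnotation(replicons=replicons, genes=genes)


_GFF3_TYPE_BY_CLASS = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "sRNA": "sRNA",
    "other_ncRNA": "ncRNA",
}


def write_genome_annotation(annotation: GenomeAnnotation, fasta_path, gff3_path) -> None:
    """Write the model back to FASTA + GFF3 (round-trips with the parser)."""
    with open(fasta_path, "w") as fh:
        for rep in annotation.replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.sequence[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in annotation.replicons:
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.replicon_id,
                        "primatx",
                        _GFF3_TYPE_BY_CLASS[g.feature_class],
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def extract_five_prime_utr(
    annotation: GenomeAnnotation, gene_id: str, tss_position: int
) -> tuple[str, int]:
    """5'-UTR sequence (transcribed strand) and length for a TSS serving a gene.

    Length is the distance in nt from the TSS to the base before the start
    codon; a TSS at the start codon gives length 0 and an empty sequence.
    A TSS downstream of the start codon is not a 5'-UTR and raises.
    """
    gene = annotation.gene(gene_id)
    rep = annotation.replicon(gene.replicon_id)
    if gene.strand == "+":
        length = gene.start - tss_position
        if length < 0:
            raise ValueError(
                f"TSS {tss_position} is downstream of the start codon of "
                f"{gene_id} (start {gene.start}, + strand): not a 5'-UTR"
            )
        seq = rep.sequence[tss_position - 1 : gene.start - 1]
    else:
        length = tss_position - gene.end
        if length < 0:
            raise ValueError(
                f"TSS {tss_position} is downstream of the start codon of "
                f"{gene_id} (start {gene.end}, - strand): not a 5'-UTR"
            )
        seq = str(Seq(rep.sequence[gene.end : tss_position]).reverse_complement())
    return seq, length


def extract_promoter_region(
    annotation: GenomeAnnotation,
    replicon_id: str,
    tss_position: int,
    strand: str,
    window: int = 200,
) -> tuple[str, bool]:
    """Sequence of `window` nt ending at TSS-1 on the TSS strand.

    Returns (sequence, truncated): the window is clipped at the replicon
    edge, in which case the truncation flag is set.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rep = annotation.replicon(replicon_id)
    if not 1 <= tss_position <= rep.length:
        raise ValueError(
            f"TSS {tss_position} outside replicon {replicon_id} (1..{rep.length})"
        )
    if strand == "+":
        lo = max(1, tss_position - window)
        seq = rep.sequence[lo - 1 : tss_position - 1]
        truncated = tss_position - window < 1
    else:
        hi = min(rep.length, tss_position + window)
        seq = str(Seq(rep.sequence[tss_position:hi]).reverse_complement())
        truncated = tss_position + window > rep.length
    return seq, truncated
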