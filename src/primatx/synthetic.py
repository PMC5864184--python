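"""Synthetic dRNA-seq study generator with planted ground truth.

Generates an annotated bacterial genome, plants TSSs of the four
categories with realistic 5'-UTR and expression distributions, and
simulates the full library design the analysis consumes: per condition
(A/B) and replicate, a TEX track carrying NB-distributed 5'-end tags at
the planted TSSs (with positional jitter), a MINUS track carrying a
leakage fraction of the TSS signal plus Poisson "processed-site"
background peaks, and one pooled RNA-seq coverage track with plateaus
from each TSS to its transcript end (what the coverage-extension
classification rule consumes).

Every stage is deterministic under a fixed seed; each stage derives its
own substream so the operations can be re-run independently.

Category mix and the UTR median mirror the census structure of a real
marine-bacterium primary transcriptome (gTSS-dominated, median 5'-UTR
63 nt); dispersion, leakage and background defaults are this package's
own choices, documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .end_coverage import EndCountTrack, LibraryMeta, write_end_count_track
from .genome_model import (
    GeneFeature,
    GenomeAnnotation,
    Replicon,
    write_genome_annotation,
)
from .tss_annotation import ClassificationConfig, classify_tss, _GeneIndex
from .tss_detection import TSSCall

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 42
    genome_length: int = 200_000
    n_genes: int = 150
    ncrna_fraction: float = 0.05
    gene_length_mean: float = 900.0
    gene_length_sd: float = 200.0
    gene_length_min: int = 150
    min_intergenic: int = 150

    n_tss: int = 200
    # category mix mirroring a gTSS-dominated bacterial census
    category_mix: dict = field(
        default_factory=lambda: {"gTSS": 0.59, "iTSS": 0.27, "aTSS": 0.06, "nTSS": 0.08}
    )
    utr_median: float = 63.0
    utr_sigma: float = 0.6
    utr_cap: int = 400

    expression_median: float = 50.0   # tags per library at a TSS
    expression_sigma: float = 0.5
    expression_floor: float = 20.0    # planted TSSs emulate detectable promoters
    nb_dispersion: float = 0.2
    tex_leakage_to_minus: float = 0.1
    processed_site_rate_per_kb: float = 2.0
    processed_site_mean: float = 30.0
    jitter: dict = field(
        default_factory=lambda: {0: 0.8, -1: 0.075, 1: 0.075, -2: 0.025, 2: 0.025}
    )
    fraction_differential: float = 0.15
    logfc_magnitudes: tuple = (1.0, 2.0, 3.0)
    # planted TSSs closer than the detector's clustering resolution
    # (cluster distance + jitter span) would collapse into one call; keep
    # planted sites resolvable as distinct promoters
    min_tss_separation: int = 10
    rnaseq_plateau_height: int = 10
    nontarget_transcript_length: int = 200  # plateau span for aTSS/nTSS
    replicon_id: str = "chromosome"
    deterministic_counts: bool = False  # noise-free: tags = round(mean), no sampling

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category mix must sum to 1")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if abs(sum(self.jitter.values()) - 1.0) > 1e-9:
            raise ValueError("jitter kernel must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["logfc_magnitudes"] = list(d["logfc_magnitudes"])
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PlantedTSS:
    replicon: str
    position: int
    strand: str
    category: str
    gene_id: Optional[str]
    utr_length: Optional[int]
    mean_a: float
    mean_b: float
    logfc: float  # planted log2 fold change, B vs A


@dataclass
class SyntheticTruth:
    tss: list[PlantedTSS]
    config: SimulationConfig


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_annotated_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Random genome with non-overlapping genes and interspersed ncRNAs."""
    rng = _rng(config, 0)
    seq = "".join(_BASES[rng.integers(0, 4, config.genome_length)])
    replicon = Replicon(config.replicon_id, config.genome_length, seq)
    if config.n_genes == 0:
        return GenomeAnnotation([replicon], [])

    n_nc = int(round(config.n_genes * config.ncrna_fraction))
    n_cds = config.n_genes - n_nc
    lengths = np.clip(
        rng.normal(config.gene_length_mean, config.gene_length_sd, n_cds),
        config.gene_length_min,
        None,
    ).astype(int)
    nc_lengths = rng.integers(80, 300, n_nc)
    all_lengths = np.concatenate([lengths, nc_lengths])
    classes = ["CDS"] * n_cds + [
        str(rng.choice(["tRNA", "sRNA"])) for _ in range(n_nc)
    ]
    order = rng.permutation(config.n_genes)
    all_lengths = all_lengths[order]
    classes = [classes[i] for i in order]

    n = config.n_genes
    occupied = int(all_lengths.sum())
    slack = config.genome_length - occupied - (n + 1) * config.min_intergenic
    if slack < 0:
        raise ValueError(
            "genome too short for the requested genes at minimum spacing; "
            "reduce n_genes or gene lengths"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    gaps = extra + config.min_intergenic

    genes: list[GeneFeature] = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor + 1
        end = start + int(all_lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(
                gene_id=f"gene_{i + 1:04d}",
                replicon_id=config.replicon_id,
                start=start,
                end=end,
                strand=strand,
                feature_class=classes[i],
            )
        )
        cursor = end
    return GenomeAnnotation([replicon], genes)


def _planting_config(config: SimulationConfig) -> ClassificationConfig:
    # planting verifies categories with the gTSS window widened to the UTR
    # cap, so long-UTR gTSSs verify and nothing is planted that the
    # coverage-extended analysis classification could re-assign to gTSS
    return ClassificationConfig(gtss_window=max(200, config.utr_cap))


def _classify_candidate(
    pos: int,
    strand: str,
    annotation: GenomeAnnotation,
    cls_config: ClassificationConfig,
    index: _GeneIndex,
):
    call = TSSCall(
        replicon=annotation.replicons[0].id,
        position=pos,
        strand=strand,
        active_conditions={"A"},
    )
    return classify_tss(call, annotation, cls_config, _index=index)


def plant_tss_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> SyntheticTruth:
    """Plant TSSs so a classifier assigns each its intended category.

    Every candidate placement is verified against the package classifier
    (gTSS window widened to the UTR cap, matching the coverage-extended
    analysis behaviour); a failed placement is resampled, with a hard
    error after 1000 attempts per TSS.
    """
    rng = _rng(config, 1)
    rep = annotation.replicons[0]
    cls_config = _planting_config(config)
    index = _GeneIndex(annotation, cls_config.atss_flank)
    cds_genes = [g for g in annotation.genes if g.is_coding]
    all_genes = annotation.genes
    categories = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in categories])
    used: set[tuple[int, str]] = set()

    planted: list[PlantedTSS] = []
    for _ in range(config.n_tss):
        category = categories[rng.choice(len(categories), p=probs)]
        if category == "gTSS" and not cds_genes:
            raise ValueError("cannot plant gTSS without CDS genes")
        placed = None
        for _attempt in range(1000):
            if category == "gTSS":
                gene = cds_genes[rng.integers(len(cds_genes))]
                d = int(
                    np.clip(
                        round(rng.lognormal(np.log(config.utr_median), config.utr_sigma)),
                        1,
                        config.utr_cap,
                    )
                )
                pos = gene.start - d if gene.strand == "+" else gene.end + d
                strand = gene.strand
            elif category == "iTSS":
                gene = all_genes[rng.integers(len(all_genes))]
                pos = int(rng.integers(gene.start, gene.end + 1))
                strand = gene.strand
            elif category == "aTSS":
                gene = all_genes[rng.integers(len(all_genes))]
                pos = int(
                    rng.integers(gene.start - cls_config.atss_flank,
                                 gene.end + cls_config.atss_flank + 1)
                )
                strand = "-" if gene.strand == "+" else "+"
            else:  # nTSS
                gene = None
                pos = int(rng.integers(1, rep.length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
            sep = config.min_tss_separation
            if not 1 <= pos <= rep.length or any(
                (pos + d, strand) in used for d in range(-sep, sep + 1)
            ):
                continue
            record = _classify_candidate(pos, strand, annotation, cls_config, index)
            if record.category != category:
                continue
            if category == "gTSS" and (
                record.associated_gene_id != gene.gene_id or record.utr_length != d
            ):
                continue
            placed = (pos, strand, record)
            break
        if placed is None:
            raise RuntimeError(
                f"could not place a {category} after 1000 attempts; the gene "
                f"layout may be too dense for this category"
            )
        pos, strand, record = placed
        used.add((pos, strand))
        mean_a = max(
            config.expression_floor,
            rng.lognormal(np.log(config.expression_median), config.expression_sigma),
        )
        logfc = 0.0
        if rng.random() < config.fraction_differential:
            mag = config.logfc_magnitudes[rng.integers(len(config.logfc_magnitudes))]
            logfc = float(mag if rng.random() < 0.5 else -mag)
        mean_b = mean_a * 2.0**logfc
        planted.append(
            PlantedTSS(
                replicon=rep.id,
                position=pos,
                strand=strand,
                category=category,
                gene_id=record.associated_gene_id,
                utr_length=record.utr_length,
                mean_a=float(mean_a),
                mean_b=float(mean_b),
                logfc=logfc,
            )
        )
    planted.sort(key=lambda t: (t.strand, t.position))
    return SyntheticTruth(tss=planted, config=config)


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi < 1e-8:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mean)))


def _spread(
    rng: np.random.Generator,
    track: EndCountTrack,
    replicon: str,
    strand: str,
    pos: int,
    total: int,
    jitter: dict,
    genome_length: int,
) -> None:
    if total <= 0:
        return
    offsets = sorted(jitter)
    probs = np.array([jitter[o] for o in offsets])
    split = rng.multinomial(total, probs)
    for off, cnt in zip(offsets, split):
        p = pos + off
        if 1 <= p <= genome_length and cnt > 0:
            track.add(replicon, strand, p, int(cnt))


def _transcript_span(
    t: PlantedTSS, annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[int, int]:
    """Genomic span covered by the transcript starting at a planted TSS."""
    L = annotation.replicons[0].length
    if t.gene_id is not None:
        g = annotation.gene(t.gene_id)
        lo, hi = (t.position, g.end) if t.strand == "+" else (g.start, t.position)
    else:
        n = config.nontarget_transcript_length
        if t.strand == "+":
            lo, hi = t.position, t.position + n - 1
        else:
            lo, hi = t.position - n + 1, t.position
    return max(1, lo), min(L, hi)


def simulate_end_counts(
    truth: SyntheticTruth,
    annotation: GenomeAnnotation,
    config: SimulationConfig | None = None,
) -> list[EndCountTrack]:
    """Simulate TEX/MINUS tracks (2 conditions x 2 replicates) + pooled RNA-seq.

    Per TSS and library, TEX tags are NB(mean_condition, phi) spread by
    the positional jitter kernel. MINUS receives a Poisson leakage
    fraction of the TSS mean plus shared processed-site background peaks
    (site positions drawn once, at least 5 nt away from any planted TSS;
    per-library Poisson counts). The pooled RNA-seq track adds a
    deterministic coverage plateau over each planted transcript.
    """
    config = config or truth.config
    rng = _rng(config, 2)
    rep_id = annotation.replicons[0].id
    L = annotation.replicons[0].length

    # shared processed-site positions, away from planted TSS neighbourhoods
    tss_shadow = {
        (p, s)
        for t in truth.tss
        for s in (t.strand,)
        for p in range(t.position - 5, t.position + 6)
    }
    n_sites = rng.poisson(config.processed_site_rate_per_kb * L / 1000.0)
    sites: list[tuple[int, str]] = []
    while len(sites) < n_sites:
        p = int(rng.integers(1, L + 1))
        s = "+" if rng.random() < 0.5 else "-"
        if (p, s) not in tss_shadow:
            sites.append((p, s))

    tracks: list[EndCountTrack] = []
    for cond in ("A", "B"):
        for replicate in (1, 2):
            tex = EndCountTrack(
                LibraryMeta(f"TEX_{cond}{replicate}", cond, replicate, "TEX")
            )
            minus = EndCountTrack(
                LibraryMeta(f"MINUS_{cond}{replicate}", cond, replicate, "MINUS")
            )
            for t in truth.tss:
                mu = t.mean_a if cond == "A" else t.mean_b
                if config.deterministic_counts:
                    n_tex = int(round(mu))
                    n_leak = int(round(config.tex_leakage_to_minus * mu))
                else:
                    n_tex = _nb_draw(rng, mu, config.nb_dispersion)
                    n_leak = int(rng.poisson(config.tex_leakage_to_minus * mu))
                _spread(rng, tex, rep_id, t.strand, t.position, n_tex, config.jitter, L)
                _spread(
                    rng, minus, rep_id, t.strand, t.position, n_leak, config.jitter, L
                )
            for p, s in sites:
                c = int(rng.poisson(config.processed_site_mean))
                if c > 0:
                    minus.add(rep_id, s, p, c)
            tracks.append(tex)
            tracks.append(minus)

    rnaseq = EndCountTrack(LibraryMeta("RNASEQ_pooled", "A", 1, "RNASEQ"))
    for t in truth.tss:
        lo, hi = _transcript_span(t, annotation, config)
        for p in range(lo, hi + 1):
            rnaseq.add(rep_id, t.strand, p, config.rnaseq_plateau_height)
    tracks.append(rnaseq)
    return tracks


def simulate_bundle(
    config: SimulationConfig | None = None,
) -> tuple[GenomeAnnotation, SyntheticTruth, list[EndCountTrack]]:
    """Convenience: genome -> planted truth -> simulated tracks."""
    config = config or SimulationConfig()
    annotation = generate_annotated_genome(config)
    truth = plant_tss_truth(annotation, config)
    tracks = simulate_end_counts(truth, annotation, config)
    return annotation, truth, tracks


def write_fixture_bundle(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    tracks: list[EndCountTrack],
    out_dir,
    force: bool = False,
) -> dict:
    """Write FASTA, GFF3, bedGraph pairs, truth TSV and a manifest to disk."""
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True to overwrite)")
    os.makedirs(out_dir, exist_ok=True)
    write_genome_annotation(
        annotation,
        os.path.join(out_dir, "genome.fasta"),
        os.path.join(out_dir, "annotation.gff3"),
    )
    totals = {}
    for track in tracks:
        lib = track.meta.library_id
        write_end_count_track(
            track,
            os.path.join(out_dir, f"{lib}.plus.bedgraph"),
            os.path.join(out_dir, f"{lib}.minus.bedgraph"),
        )
        totals[lib] = track.total_count
    with open(os.path.join(out_dir, "tss_truth.tsv"), "w") as fh:
        fh.write(
            "replicon\tposition\tstrand\tcategory\tgene_id\tutr_length\t"
            "mean_a\tmean_b\tlogfc\n"
        )
        for t in truth.tss:
            fh.write(
                f"{t.replicon}\t{t.position}\t{t.strand}\t{t.category}\t"
                f"{t.gene_id or '.'}\t"
                f"{t.utr_length if t.utr_length is not None else '.'}\t"
                f"{t.mean_a:.4f}\t{t.mean_b:.4f}\t{t.logfc:g}\n"
            )
    manifest = {
        "seed": truth.config.seed,
        "config_hash": truth.config.content_hash(),
        "library_totals": totals,
        "n_tss": len(truth.tss),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def evaluate_detection(
    calls, truth: SyntheticTruth, tolerance: int = 5
) -> dict[str, float]:
    """Recall/precision of TSS calls against planted truth (+-tolerance nt)."""
    truth_pos: dict[str, list[int]] = {}
    for t in truth.tss:
        truth_pos.setdefault(f"{t.replicon}:{t.strand}", []).append(t.position)
    for v in truth_pos.values():
        v.sort()

    def matches_truth(call) -> bool:
        arr = truth_pos.get(f"{call.replicon}:{call.strand}", [])
        i = np.searchsorted(arr, call.position)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - call.position) <= tolerance:
                return True
        return False

    call_pos: dict[str, list[int]] = {}
    for c in calls:
        call_pos.setdefault(f"{c.replicon}:{c.strand}", []).append(c.position)
    for v in call_pos.values():
        v.sort()

    def recovered(t: PlantedTSS) -> bool:
        arr = call_pos.get(f"{t.replicon}:{t.strand}", [])
        i = np.searchsorted(arr, t.position)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - t.position) <= tolerance:
                return True
        return False

    n_truth = len(truth.tss)
    n_calls = len(list(calls))
    recall = sum(recovered(t) for t in truth.tss) / n_truth if n_truth else 1.0
    precision = sum(matches_truth(c) for c in calls) / n_calls if n_calls else 1.0
    return {"recall": recall, "precision": precision, "n_calls": n_calls}
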