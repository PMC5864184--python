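"""TSS calling from TEX+/MINUS 5'-end enrichment.

The detector contrasts, per genomic position, the depth-scaled 5'-end
count of the TEX-treated library (enriched for primary, 5'PPP ends)
against the matched MINUS library (left-over processed 5'P ends, the
background). Replicates assist the background subtraction: a position
becomes a candidate in a condition only when its TEX/background
enrichment passes the threshold under the configured replicate rule
(default: in *both* replicates). Candidates are clustered to absorb
5'-end jitter, conditions are detected independently, and the final TSS
set is the cluster-merged union over conditions — mirroring a census
that reports per-condition TSS sets plus a total.

All thresholds are explicit configuration; the defaults are this
package's own choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .end_coverage import EndCountTrack, scale_to_common_depth

REPLICATE_RULES = ("both", "any", "any_strong")


@dataclass
class DetectionConfig:
    min_height: int = 10          # raw TEX 5'-end reads required at a position
    min_enrichment: float = 2.0   # scaled TEX / (scaled MINUS + pseudocount)
    pseudocount: float = 1.0
    cluster_distance: int = 5     # nt; jittered 5' ends within this merge
    replicate_rule: str = "both"
    strong_enrichment: float = 5.0

    def __post_init__(self) -> None:
        if self.min_height < 1:
            raise ValueError("min_height must be >= 1")
        if self.min_enrichment <= 1:
            raise ValueError("min_enrichment must be > 1")
        if self.cluster_distance < 0:
            raise ValueError("cluster_distance must be >= 0")
        if self.replicate_rule not in REPLICATE_RULES:
            raise ValueError(f"replicate_rule must be one of {REPLICATE_RULES}")


@dataclass
class CandidatePosition:
    replicon: str
    position: int
    strand: str
    tex_count: dict[int, int]          # replicate -> raw TEX count
    background: dict[int, float]       # replicate -> scaled MINUS count
    enrichment: dict[int, float]       # replicate -> TEX/background enrichment
    signal: dict[int, float]           # replicate -> max(0, scaled TEX - scaled MINUS)


@dataclass
class TSSCall:
    replicon: str
    position: int
    strand: str
    active_conditions: set[str]
    tag_counts: dict[str, int] = field(default_factory=dict)  # library_id -> tags


def compute_position_enrichment(
    tex_tracks: dict[int, EndCountTrack],
    minus_tracks: dict[int, EndCountTrack],
    scale_factors: dict[str, float],
    config: DetectionConfig,
) -> list[CandidatePosition]:
    """Per-position TEX-vs-background enrichment for one condition.

    tex_tracks / minus_tracks map replicate number -> track. A position is
    emitted when its raw TEX count reaches ``min_height`` in at least one
    replicate; enrichment is computed per replicate as
    scaled_tex / (scaled_minus + pseudocount).
    """
    replicates = sorted(tex_tracks)
    keys = set()
    for t in tex_tracks.values():
        keys.update(t.counts.keys())
    out: list[CandidatePosition] = []
    for (replicon, strand) in sorted(keys):
        positions = set()
        for rep in replicates:
            posmap = tex_tracks[rep].positions(replicon, strand)
            positions.update(p for p, c in posmap.items() if c >= config.min_height)
        for pos in sorted(positions):
            tex_raw, bg, enr, sig = {}, {}, {}, {}
            for rep in replicates:
                tex = tex_tracks[rep].get(replicon, strand, pos)
                minus = minus_tracks[rep].get(replicon, strand, pos)
                f_tex = scale_factors[tex_tracks[rep].meta.library_id]
                f_minus = scale_factors[minus_tracks[rep].meta.library_id]
                s_tex = tex * f_tex
                s_minus = minus * f_minus
                tex_raw[rep] = tex
                bg[rep] = s_minus
                enr[rep] = s_tex / (s_minus + config.pseudocount)
                sig[rep] = max(0.0, s_tex - s_minus)
            out.append(
                CandidatePosition(replicon, pos, strand, tex_raw, bg, enr, sig)
            )
    return out


def _passes(candidate: CandidatePosition, config: DetectionConfig) -> bool:
    # min_height gates candidate *emission*; the replicate rule judges
    # enrichment only.
    enr = candidate.enrichment
    ok = {rep: enr[rep] >= config.min_enrichment for rep in enr}
    strong = {rep: enr[rep] >= config.strong_enrichment for rep in enr}
    if config.replicate_rule == "both":
        return all(ok.values())
    if config.replicate_rule == "any":
        return any(ok.values())
    return all(ok.values()) or any(strong.values())


def call_candidates(
    candidates: list[CandidatePosition], config: DetectionConfig
) -> list[CandidatePosition]:
    """Apply the replicate decision rule to candidate positions."""
    if candidates and config.replicate_rule != "any":
        n_reps = {len(c.enrichment) for c in candidates}
        if min(n_reps) < 2:
            raise ValueError(
                "replicate rule "
                f"{config.replicate_rule!r} needs both replicates present"
            )
    return [c for c in candidates if _passes(c, config)]


def cluster_candidates(
    passing: list[CandidatePosition], config: DetectionConfig
) -> list[CandidatePosition]:
    """Collapse runs of nearby passing positions to one representative.

    A position joins the current cluster when it lies within
    ``cluster_distance`` nt of the previous member. The representative is
    the member with the largest summed TEX count over replicates; ties go
    to the 5'-most member (smallest coordinate on +, largest on -).
    """
    by_key: dict[tuple[str, str], list[CandidatePosition]] = {}
    for c in passing:
        by_key.setdefault((c.replicon, c.strand), []).append(c)
    out: list[CandidatePosition] = []
    for (replicon, strand), group in sorted(by_key.items()):
        group.sort(key=lambda c: c.position)
        cluster: list[CandidatePosition] = []
        for c in group:
            if cluster and c.position - cluster[-1].position <= config.cluster_distance:
                cluster.append(c)
            else:
                if cluster:
                    out.append(_representative(cluster, strand))
                cluster = [c]
        if cluster:
            out.append(_representative(cluster, strand))
    out.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return out


def _representative(cluster: list[CandidatePosition], strand: str) -> CandidatePosition:
    def score(c: CandidatePosition):
        total = sum(c.tex_count.values())
        # tie-break 5'-most: smaller position on +, larger on -
        tiebreak = -c.position if strand == "+" else c.position
        return (total, tiebreak)

    return max(cluster, key=score)


def consolidate_condition_tss(
    clustered_by_condition: dict[str, list[CandidatePosition]],
    config: DetectionConfig,
) -> list[TSSCall]:
    """Merge per-condition clustered calls into the global TSS set.

    Calls from different conditions within ``cluster_distance`` merge into
    one TSSCall whose representative position comes from the condition
    with the higher summed TEX count; ``active_conditions`` records every
    condition that contributed.
    """
    entries = []  # (replicon, strand, position, condition, total_count)
    for cond, calls in clustered_by_condition.items():
        for c in calls:
            entries.append(
                (c.replicon, c.strand, c.position, cond, sum(c.tex_count.values()))
            )
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    out: list[TSSCall] = []
    cluster: list[tuple] = []

    def flush(cluster):
        best = max(cluster, key=lambda e: (e[4], -e[2] if e[1] == "+" else e[2]))
        out.append(
            TSSCall(
                replicon=best[0],
                position=best[2],
                strand=best[1],
                active_conditions={e[3] for e in cluster},
            )
        )

    for e in entries:
        if (
            cluster
            and e[0] == cluster[-1][0]
            and e[1] == cluster[-1][1]
            and e[2] - cluster[-1][2] <= config.cluster_distance
        ):
            cluster.append(e)
        else:
            if cluster:
                flush(cluster)
            cluster = [e]
    if cluster:
        flush(cluster)
    out.sort(key=lambda c: (c.replicon, c.strand, c.position))
    return out


def detect_tss(
    tracks: list[EndCountTrack], config: DetectionConfig | None = None
) -> list[TSSCall]:
    """End-to-end detection over all supplied TEX/MINUS tracks.

    Tracks are grouped by (condition, replicate); depth scale factors are
    computed jointly over all TEX and MINUS libraries. RNASEQ tracks are
    ignored here. Per-library tag counts within +-cluster_distance of each
    final call are attached to the returned TSSCalls.
    """
    config = config or DetectionConfig()
    tex: dict[str, dict[int, EndCountTrack]] = {}
    minus: dict[str, dict[int, EndCountTrack]] = {}
    used = []
    for t in tracks:
        if t.meta.treatment == "TEX":
            tex.setdefault(t.meta.condition, {})[t.meta.replicate] = t
            used.append(t)
        elif t.meta.treatment == "MINUS":
            minus.setdefault(t.meta.condition, {})[t.meta.replicate] = t
            used.append(t)
    for cond, reps in tex.items():
        for rep in reps:
            if cond not in minus or rep not in minus[cond]:
                raise ValueError(
                    f"condition {cond} replicate {rep}: TEX library has no "
                    f"matched MINUS library"
                )
    # empty MINUS libraries (e.g. noise-free simulations) contribute no
    # background; give them a neutral factor instead of failing depth scaling
    nonzero = [t for t in used if t.total_count > 0]
    factors = {t.meta.library_id: 1.0 for t in used}
    if len(nonzero) >= 2:
        factors.update(scale_to_common_depth(nonzero))
    clustered = {}
    for cond in sorted(tex):
        cands = compute_position_enrichment(tex[cond], minus[cond], factors, config)
        passing = call_candidates(cands, config)
        clustered[cond] = cluster_candidates(passing, config)
    calls = consolidate_condition_tss(clustered, config)
    # attach per-library tag counts in a +-cluster_distance window
    all_tex = [t for reps in tex.values() for t in reps.values()]
    for call in calls:
        for t in all_tex:
            posmap = t.positions(call.replicon, call.strand)
            w = config.cluster_distance
            call.tag_counts[t.meta.library_id] = sum(
                posmap.get(p, 0) for p in range(call.position - w, call.position + w + 1)
            )
    return calls
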