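"""Differential promoter activity between two conditions, per TSS.

The model: tag counts y_ij for TSS i in library j are negative binomial
with a common dispersion phi (var = mu + phi mu^2). Libraries are scaled
by TMM (trimmed mean of M-values) normalization factors; the common phi
is estimated by conditional maximum likelihood after mean-scaling counts
to a common effective library size; and each TSS is tested with the
two-group NB exact test, conditioning on the TSS's total count. The
quantile-adjusted equalization used by edgeR's qCML is approximated here
by plain mean scaling of counts to the common effective size -- a
documented approximation, so small numeric divergence from edgeR is
expected.

Two-sided p-values sum the probabilities of all splits of the total at
most as likely as the observed split (doubling the smaller tail is not
used); phi = 0 reduces to the conditional binomial exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .end_coverage import EndCountTrack
from .tss_annotation import TSSRecord

logger = logging.getLogger(__name__)

_PHI_MIN, _PHI_MAX = 1e-6, 10.0
_TIE_REL_TOL = 1e-9  # splits within this relative pmf tolerance count as ties


@dataclass
class TMMConfig:
    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    weighting: bool = True

    def __post_init__(self) -> None:
        for t in (self.logratio_trim, self.abs_expr_trim):
            if not 0 <= t < 0.5:
                raise ValueError("trims must lie in [0, 0.5)")


@dataclass
class DiffExpConfig:
    fdr_cutoff: float = 0.05
    min_abs_logfc: float = 1.0
    prior_count: float = 0.5
    count_window: int = 5  # nt, matches the detection cluster distance

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0,1)")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")


@dataclass
class DiffExpResult:
    tss_id: str
    counts: dict[str, int]
    logfc: float   # condition B vs A, log2
    p_value: float
    fdr: float
    call: str      # up / down / unchanged


def count_tss_tags(
    tss_records: Sequence[TSSRecord],
    tex_tracks: Sequence[EndCountTrack],
    count_window: int = 5,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Count matrix TSS x library: raw TEX 5'-end tags within +-count_window.

    When the windows of two TSSs on a strand overlap, each position's
    tags go to the nearer TSS (tie -> the upstream one), so no tag is
    counted twice and column sums over assigned positions are conserved.
    Returns (matrix, tss_ids, library_ids).
    """
    tss_ids = [r.tss_id for r in tss_records]
    lib_ids = [t.meta.library_id for t in tex_tracks]
    mat = np.zeros((len(tss_records), len(tex_tracks)), dtype=np.int64)

    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, r in enumerate(tss_records):
        by_key.setdefault((r.replicon, r.strand), []).append((r.position, i))
    for (replicon, strand), tss_list in by_key.items():
        tss_list.sort()
        positions = np.array([p for p, _ in tss_list])
        for j, track in enumerate(tex_tracks):
            posmap = track.positions(replicon, strand)
            for pos, cnt in posmap.items():
                k = int(np.searchsorted(positions, pos))
                best_i, best_d = None, None
                for idx in (k - 1, k):
                    if not 0 <= idx < len(tss_list):
                        continue
                    d = abs(pos - int(positions[idx]))
                    if d > count_window:
                        continue
                    if (
                        best_d is None
                        or d < best_d
                        or (
                            d == best_d
                            and _is_upstream(
                                int(positions[idx]), int(positions[best_i]), strand
                            )
                        )
                    ):
                        best_i, best_d = idx, d
                if best_i is not None:
                    mat[tss_list[best_i][1], j] += cnt
    # log overlapping windows once
    for (replicon, strand), tss_list in by_key.items():
        for (p1, _), (p2, _) in zip(tss_list, tss_list[1:]):
            if p2 - p1 <= 2 * count_window:
                logger.info(
                    "overlapping TSS count windows at %s:%d/%d (%s): tags "
                    "assigned to the nearer TSS",
                    replicon,
                    p1,
                    p2,
                    strand,
                )
    return mat, tss_ids, lib_ids


def _is_upstream(pos_a: int, pos_b: int, strand: str) -> bool:
    """True when pos_a is 5' of pos_b on the given strand."""
    return pos_a < pos_b if strand == "+" else pos_a > pos_b


def tmm_normalization_factors(
    count_matrix: np.ndarray,
    config: TMMConfig | None = None,
    lib_sizes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference library is the one whose upper-quartile expression
    (counts/library size) is closest to the mean upper quartile. For each
    library, M (log2 ratio vs reference) and A (average log2 expression)
    are computed over features nonzero in both; features in the most
    extreme ``logratio_trim`` tails of M and ``abs_expr_trim`` tails of A
    are removed; the factor is 2 to the (inverse-variance weighted) mean
    of the surviving M values.
    """
    config = config or TMMConfig()
    x = np.asarray(count_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a features x libraries matrix with >= 2 libraries")
    if lib_sizes is None:
        lib_sizes = x.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes == 0):
        raise ValueError(
            f"library {int(np.where(lib_sizes == 0)[0][0])} has all-zero counts"
        )
    f75 = np.array(
        [np.quantile(x[:, j] / lib_sizes[j], 0.75) for j in range(x.shape[1])]
    )
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(x.sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        factors[j] = _tmm_pair(
            x[:, j], x[:, ref], lib_sizes[j], lib_sizes[ref], config
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, config: TMMConfig) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    log_r = np.log2(p_obs / p_ref)
    abs_e = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * config.logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * config.abs_expr_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not np.any(keep):
        return 1.0
    if config.weighting:
        f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def _scale_to_common_size(
    counts: np.ndarray, effective_sizes: np.ndarray
) -> np.ndarray:
    """Mean-scale each column to the geometric-mean effective size."""
    ref = np.exp(np.mean(np.log(effective_sizes)))
    return counts * (ref / effective_sizes)[None, :]


def estimate_common_dispersion(
    count_matrix: np.ndarray,
    groups: Sequence[str],
    effective_sizes: Optional[np.ndarray] = None,
) -> float:
    """Common NB dispersion phi by conditional maximum likelihood.

    ``groups`` labels each column; the conditional likelihood (given each
    feature's within-group total) is summed over groups with >= 2
    samples, after mean-scaling counts to the common effective size.
    Returns phi clipped to [1e-6, 10].
    """
    x = np.asarray(count_matrix, dtype=float)
    if x.size == 0 or not np.any(x > 0):
        raise ValueError("all-zero count matrix")
    groups = np.asarray(groups)
    if effective_sizes is None:
        effective_sizes = x.sum(axis=0)
    y = _scale_to_common_size(x, np.asarray(effective_sizes, dtype=float))

    blocks = []
    for g in np.unique(groups):
        cols = np.where(groups == g)[0]
        if cols.size >= 2:
            sub = y[:, cols]
            sub = sub[sub.sum(axis=1) > 0]
            if sub.size:
                blocks.append(sub)
    if not blocks:
        raise ValueError("need at least one group with >= 2 samples")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for sub in blocks:
            n = sub.shape[1]
            z = sub.sum(axis=1)
            ll = (
                gammaln(sub + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
            total += ll.sum()
        return -total

    res = minimize_scalar(
        neg_cll,
        bounds=(np.log(_PHI_MIN), np.log(_PHI_MAX)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.clip(np.exp(res.x), _PHI_MIN, _PHI_MAX))


def nb_exact_test(
    count_a: Sequence[int],
    count_b: Sequence[int],
    effective_sizes: Sequence[float],
    phi: float,
) -> float:
    """Two-sided exact NB test between two groups of counts.

    ``effective_sizes`` lists the per-library effective sizes in the
    order count_a + count_b; counts are mean-scaled to the common size
    and rounded before conditioning on the total s. The p-value sums
    P(split) over all splits (a, s-a) with probability at most that of
    the observed split; phi = 0 degenerates to a conditional binomial.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    sizes = np.asarray(effective_sizes, dtype=float)
    if sizes.size != a.size + b.size:
        raise ValueError("effective_sizes must cover both groups")
    ref = np.exp(np.mean(np.log(sizes)))
    scaled = np.rint(np.concatenate([a, b]) * (ref / sizes)).astype(np.int64)
    a_obs = int(scaled[: a.size].sum())
    s = int(scaled.sum())
    if s == 0:
        return 1.0
    n_a, n_b = a.size, b.size
    ks = np.arange(s + 1)
    if phi < 1e-10:
        # Poisson limit: conditional distribution is binomial(s, n_a/(n_a+n_b))
        logp = (
            gammaln(s + 1)
            - gammaln(ks + 1)
            - gammaln(s - ks + 1)
            + ks * np.log(n_a / (n_a + n_b))
            + (s - ks) * np.log(n_b / (n_a + n_b))
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(ks + r_a)
            - gammaln(ks + 1)
            + gammaln(s - ks + r_b)
            - gammaln(s - ks + 1)
        )
        logp -= logsumexp(logp)
    p_obs = logp[a_obs]
    keep = logp <= p_obs + np.log1p(_TIE_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def call_differential_tss(
    tss_ids: Sequence[str],
    count_matrix: np.ndarray,
    cols_a: Sequence[int],
    cols_b: Sequence[int],
    p_values: Sequence[float],
    effective_sizes: np.ndarray,
    config: DiffExpConfig | None = None,
    lib_ids: Optional[Sequence[str]] = None,
) -> list[DiffExpResult]:
    """BH-adjust the p-values and call up/down/unchanged per TSS.

    logFC is log2[(mean normalized B + prior)/(mean normalized A +
    prior)] on counts scaled to the common effective size. A TSS is "up"
    when logFC >= min_abs_logfc and FDR < fdr_cutoff, "down" for the
    mirror case, else "unchanged".
    """
    config = config or DiffExpConfig()
    x = np.asarray(count_matrix, dtype=float)
    norm = _scale_to_common_size(x, np.asarray(effective_sizes, dtype=float))
    mean_a = norm[:, list(cols_a)].mean(axis=1)
    mean_b = norm[:, list(cols_b)].mean(axis=1)
    logfc = np.log2((mean_b + config.prior_count) / (mean_a + config.prior_count))
    _, fdr, _, _ = multipletests(np.asarray(p_values), method="fdr_bh")
    results = []
    for i, tss_id in enumerate(tss_ids):
        if fdr[i] < config.fdr_cutoff and logfc[i] >= config.min_abs_logfc:
            call = "up"
        elif fdr[i] < config.fdr_cutoff and logfc[i] <= -config.min_abs_logfc:
            call = "down"
        else:
            call = "unchanged"
        counts = {
            (lib_ids[j] if lib_ids else f"lib{j}"): int(x[i, j])
            for j in range(x.shape[1])
        }
        results.append(
            DiffExpResult(
                tss_id=tss_id,
                counts=counts,
                logfc=float(logfc[i]),
                p_value=float(p_values[i]),
                fdr=float(fdr[i]),
                call=call,
            )
        )
    return results


def run_differential(
    tss_records: Sequence[TSSRecord],
    tex_tracks: Sequence[EndCountTrack],
    config: DiffExpConfig | None = None,
    tmm_config: TMMConfig | None = None,
    dispersion_groups: Optional[Sequence[str]] = None,
    condition_a: str = "A",
    condition_b: str = "B",
) -> list[DiffExpResult]:
    """Full differential-promoter-activity pipeline over TEX libraries.

    By default the dispersion pools all libraries as pseudo-replicates
    (the workaround of the motivating study, appropriate when true
    replication is thin); pass ``dispersion_groups`` to group by
    condition instead.
    """
    config = config or DiffExpConfig()
    tex = [t for t in tex_tracks if t.meta.treatment == "TEX"]
    mat, tss_ids, lib_ids = count_tss_tags(tss_records, tex, config.count_window)
    keep = mat.sum(axis=1) > 0
    mat_t = mat[keep]
    ids_t = [t for t, k in zip(tss_ids, keep) if k]
    lib_sizes = mat_t.sum(axis=0).astype(float)
    factors = tmm_normalization_factors(mat_t, tmm_config)
    eff = lib_sizes * factors
    if dispersion_groups is None:
        dispersion_groups = ["pooled"] * len(tex)
    phi = estimate_common_dispersion(mat_t, dispersion_groups, eff)
    cols_a = [j for j, t in enumerate(tex) if t.meta.condition == condition_a]
    cols_b = [j for j, t in enumerate(tex) if t.meta.condition == condition_b]
    sizes_ab = np.concatenate([eff[cols_a], eff[cols_b]])
    p_values = [
        nb_exact_test(mat_t[i, cols_a], mat_t[i, cols_b], sizes_ab, phi)
        for i in range(mat_t.shape[0])
    ]
    return call_differential_tss(
        ids_t, mat_t, cols_a, cols_b, p_values, eff, config, lib_ids
    )
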