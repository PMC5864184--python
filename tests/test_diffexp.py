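"""Differential promoter activity: counting, TMM, dispersion, exact test."""

import math
import subprocess

import numpy as np
import pytest
from scipy.stats import rankdata

import primatx
from primatx.diffexp import (
    DiffExpConfig,
    TMMConfig,
    call_differential_tss,
    count_tss_tags,
    estimate_common_dispersion,
    nb_exact_test,
    tmm_normalization_factors,
)
from primatx.end_coverage import EndCountTrack, LibraryMeta
from primatx.tss_annotation import TSSRecord


def _record(pos, strand="+"):
    return TSSRecord("chr", pos, strand, {"A"}, {}, "gTSS", None, 50, False, {"gTSS"})


def _track(lib, positions, cond="A", rep=1):
    t = EndCountTrack(LibraryMeta(lib, cond, rep, "TEX"))
    for p, c in positions.items():
        t.add("chr", "+", p, c)
    return t


class TestTagCounting:
    def test_window_sum(self):
        track = _track("T", {98: 3, 99: 0, 100: 10, 101: 2, 102: 1})
        mat, ids, libs = count_tss_tags([_record(100)], [track], count_window=5)
        assert mat[0, 0] == 16

    def test_empty_track_zeros(self):
        mat, _, _ = count_tss_tags([_record(100)], [_track("T", {})])
        assert mat.sum() == 0

    def test_overlapping_windows_conserve_tags(self):
        track = _track("T", {p: 5 for p in range(96, 109)})
        mat, _, _ = count_tss_tags(
            [_record(100), _record(104)], [track], count_window=5
        )
        # every tag in 96..109 is within 5 nt of one of the TSSs; none doubled
        assert mat.sum() == 5 * 13
        assert mat[0, 0] > 0 and mat[1, 0] > 0


def tmm_oracle(x, lib_sizes, logratio_trim=0.30, abs_expr_trim=0.05):
    """Straight-from-the-formula TMM reimplementation (plain loops)."""
    x = np.asarray(x, dtype=float)
    n_lib = x.shape[1]
    f75 = [np.quantile(x[:, j] / lib_sizes[j], 0.75) for j in range(n_lib)]
    ref = min(range(n_lib), key=lambda j: abs(f75[j] - np.mean(f75)))
    factors = []
    for j in range(n_lib):
        logr, abse, var = [], [], []
        for g in range(x.shape[0]):
            o, r = x[g, j], x[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib_sizes[j], r / lib_sizes[ref]
                logr.append(math.log2(po / pr))
                abse.append(0.5 * (math.log2(po) + math.log2(pr)))
                var.append(
                    (lib_sizes[j] - o) / (lib_sizes[j] * o)
                    + (lib_sizes[ref] - r) / (lib_sizes[ref] * r)
                )
        if not logr or max(abs(v) for v in logr) < 1e-6:
            factors.append(1.0)
            continue
        n = len(logr)
        lo_l, lo_s = math.floor(n * logratio_trim) + 1, math.floor(n * abs_expr_trim) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rl, rs = rankdata(logr), rankdata(abse)
        num = den = 0.0
        for i in range(n):
            if lo_l <= rl[i] <= hi_l and lo_s <= rs[i] <= hi_s:
                num += logr[i] / var[i]
                den += 1.0 / var[i]
        factors.append(2.0 ** (num / den) if den else 1.0)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        x = np.tile(np.arange(1, 101)[:, None], (1, 4))
        assert np.allclose(tmm_normalization_factors(x), 1.0)

    def test_pure_depth_change_compensated(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(40, 300) + 1
        x = np.stack([base, 2 * base], axis=1)
        f = tmm_normalization_factors(x)
        # depth is absorbed by the library size, not the composition factor
        assert np.allclose(f, 1.0, atol=1e-9)
        eff = x.sum(axis=0) * f
        norm = x / eff[None, :]
        assert np.allclose(norm[:, 0], norm[:, 1], rtol=1e-9)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mu = rng.lognormal(4, 1, 400)
            depth = np.array([1.0, 1.8, 0.6, 1.2])
            x = rng.negative_binomial(5, 5 / (5 + mu[:, None] * depth), (400, 4))
            sizes = x.sum(axis=0).astype(float)
            ours = tmm_normalization_factors(x)
            theirs = tmm_oracle(x, sizes)
            assert np.abs(ours - theirs).max() < 1e-8

    def test_all_zero_library_rejected(self):
        x = np.zeros((10, 2))
        x[:, 0] = 5
        with pytest.raises(ValueError, match="all-zero"):
            tmm_normalization_factors(x)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent cross-check against the R reference implementation."""
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4, 1, 500)
        x = rng.negative_binomial(
            5, 5 / (5 + mu[:, None] * np.array([1, 2, 0.7, 1.3])), (500, 4)
        )
        mat = tmp_path / "m.tsv"
        np.savetxt(mat, x, fmt="%d", delimiter="\t")
        script = (
            'suppressMessages(library(edgeR)); '
            f'x<-as.matrix(read.delim("{mat}",header=FALSE)); '
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        reference = np.array([float(v) for v in proc.stdout.split()])
        ours = tmm_normalization_factors(x)
        assert np.abs(ours - reference).max() < 1e-5


class TestDispersion:
    def test_poisson_matrix_near_zero(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(np.log(50), 0.5, 1000)
        x = rng.poisson(mu[:, None], (1000, 4))
        phi = estimate_common_dispersion(x, ["g"] * 4, np.full(4, x.sum(0).mean()))
        assert phi <= 0.01

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(7)
        mu = rng.lognormal(np.log(50), 0.5, 2000)
        r = 1 / 0.2
        x = rng.negative_binomial(r, r / (r + mu[:, None]), (2000, 4))
        phi = estimate_common_dispersion(x, ["g"] * 4, np.full(4, x.sum(0).mean()))
        assert 0.15 <= phi <= 0.25

    def test_constant_counts_hit_lower_clip(self):
        x = np.full((1, 4), 20)
        phi = estimate_common_dispersion(x, ["g"] * 4, np.full(4, 20.0))
        assert phi == pytest.approx(1e-6, rel=10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_common_dispersion(np.zeros((5, 4)), ["g"] * 4)


def exact_test_oracle(count_a, count_b, sizes, phi):
    """Full enumeration of the conditional NB split distribution."""
    ref = math.exp(sum(math.log(s) for s in sizes) / len(sizes))
    scaled = [round(c * ref / s) for c, s in zip(list(count_a) + list(count_b), sizes)]
    na, nb = len(count_a), len(count_b)
    a_obs, s = sum(scaled[:na]), sum(scaled)
    if s == 0:
        return 1.0
    lg = math.lgamma
    if phi < 1e-10:
        logp = [
            lg(s + 1) - lg(k + 1) - lg(s - k + 1)
            + k * math.log(na / (na + nb))
            + (s - k) * math.log(nb / (na + nb))
            for k in range(s + 1)
        ]
    else:
        ra, rb = na / phi, nb / phi
        logp = [
            lg(k + ra) - lg(k + 1) + lg(s - k + rb) - lg(s - k + 1)
            for k in range(s + 1)
        ]
        m = max(logp)
        z = m + math.log(sum(math.exp(v - m) for v in logp))
        logp = [v - z for v in logp]
    p_obs = logp[a_obs]
    tol = math.log1p(1e-9)
    return min(1.0, sum(math.exp(v) for v in logp if v <= p_obs + tol))


class TestExactTest:
    def test_balanced_counts_p_one(self):
        assert nb_exact_test([10, 10], [10, 10], [1e6] * 4, 0.2) == 1.0

    def test_binomial_closed_form_extreme(self):
        p = nb_exact_test([0, 0], [10, 10], [1e6] * 4, 0.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_enumeration_oracle_small_totals(self):
        rng = np.random.default_rng(1)
        for _ in range(400):
            phi = float(rng.choice([0.0, 0.01, 0.1, 0.5, 2.0]))
            ca = rng.integers(0, 50, 2)
            cb = rng.integers(0, 50, 2)
            sizes = rng.uniform(5e3, 2e4, 4)
            ours = nb_exact_test(ca, cb, sizes, phi)
            oracle = exact_test_oracle(ca, cb, sizes, phi)
            assert abs(ours - oracle) < 1e-10, (ca, cb, phi)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            ca = rng.integers(0, 80, 2)
            cb = rng.integers(0, 80, 2)
            phi = float(rng.uniform(0, 1))
            sizes = np.full(4, 1e4)
            assert nb_exact_test(ca, cb, sizes, phi) == pytest.approx(
                nb_exact_test(cb, ca, sizes, phi), abs=1e-12
            )


def bh_oracle(pvals):
    """Hand Benjamini-Hochberg: p_(i) * m / i, monotone from the largest."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestCalls:
    def test_bh_matches_hand_computation(self):
        pvals = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        x = np.tile(np.array([10, 10, 20, 20]), (10, 1))
        out = call_differential_tss(
            [str(i) for i in range(10)], x, [0, 1], [2, 3], pvals, np.full(4, 40.0)
        )
        expected = bh_oracle(pvals)
        for r, e in zip(out, expected):
            assert r.fdr == pytest.approx(e, rel=1e-12)

    def test_subthreshold_logfc_stays_unchanged(self):
        # strong significance but |logFC| < 1 must not be called
        x = np.array([[100, 100, 170, 170]])
        out = call_differential_tss(
            ["t"], x, [0, 1], [2, 3], [0.001], np.full(4, 540.0)
        )
        assert abs(out[0].logfc) < 1
        assert out[0].call == "unchanged"

    def test_condition_swap_negates_logfc(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(50, (50, 4))
        p = list(rng.uniform(0, 1, 50))
        sizes = np.full(4, float(x.sum(0).mean()))
        fwd = call_differential_tss(
            [str(i) for i in range(50)], x, [0, 1], [2, 3], p, sizes
        )
        rev = call_differential_tss(
            [str(i) for i in range(50)], x, [2, 3], [0, 1], p, sizes
        )
        for a, b in zip(fwd, rev):
            assert a.logfc == pytest.approx(-b.logfc, abs=1e-12)
            assert a.p_value == b.p_value


class TestRecovery:
    def test_planted_fold_changes_called_low_dispersion(self):
        """4-fold planted changes are recovered at low biological noise."""
        config = primatx.SimulationConfig(seed=42, nb_dispersion=0.05)
        annotation, truth, tracks = primatx.simulate_bundle(config)
        calls = primatx.detect_tss(tracks)
        records = primatx.classify_all(calls, annotation)
        results = primatx.run_differential(
            records, tracks, dispersion_groups=["A", "A", "B", "B"]
        )
        truth_by_pos = {(t.position, t.strand): t for t in truth.tss}

        def planted(r):
            _, pos, strand = r.tss_id.split(":")
            for d in range(-5, 6):
                hit = truth_by_pos.get((int(pos) + d, strand))
                if hit:
                    return hit
            return None

        total = correct = 0
        for r in results:
            t = planted(r)
            if t is not None and abs(t.logfc) >= 2:
                total += 1
                if (r.call == "up") == (t.logfc > 0) and r.call != "unchanged":
                    correct += 1
        assert total >= 10
        assert correct / total >= 0.90

    def test_sign_recovery_at_default_dispersion(self, default_bundle, default_records):
        """At default dispersion the logFC estimate recovers the planted sign."""
        _, _, truth, tracks = default_bundle
        results = primatx.run_differential(
            default_records, tracks, dispersion_groups=["A", "A", "B", "B"]
        )
        truth_by_pos = {(t.position, t.strand): t for t in truth.tss}
        sign_ok = total = wrong_direction_calls = 0
        for r in results:
            _, pos, strand = r.tss_id.split(":")
            t = next(
                (
                    truth_by_pos.get((int(pos) + d, strand))
                    for d in range(-5, 6)
                    if truth_by_pos.get((int(pos) + d, strand))
                ),
                None,
            )
            if t is None or abs(t.logfc) < 2:
                continue
            total += 1
            if np.sign(r.logfc) == np.sign(t.logfc):
                sign_ok += 1
            if r.call != "unchanged" and (r.call == "up") != (t.logfc > 0):
                wrong_direction_calls += 1
        assert total >= 10
        assert sign_ok / total >= 0.90
        assert wrong_direction_calls == 0
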