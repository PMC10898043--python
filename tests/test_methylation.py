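from fractions import Fraction
from math import comb

import numpy as np
import pytest

from rrmp.enrichment import CpGCoverageTrack
from rrmp.intervals import ElementAnnotation, GenomicInterval
from rrmp.methylation import (DMR_CONFIGS, call_dmrs, concordance,
                              differential_promoters, fisher_exact_p,
                              peak_association, window_betas, write_dmrs)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
             for x in range(lo, hi + 1)]
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    return float(sum(p for p in probs if p <= p_obs))


def make_track(entries):
    """entries: iterable of (chrom, pos, methylated_count, unmethylated_count)."""
    track = CpGCoverageTrack()
    for chrom, pos, m, u in entries:
        if m:
            track.add(chrom, pos, True, m)
        if u:
            track.add(chrom, pos, False, u)
    return track


def region_track(region_counts, cpgs_per_region=3, spacing=30, stride=500):
    """One track from per-region (methylated, unmethylated) totals, split
    evenly across the region's CpGs."""
    entries = []
    for r, (m, u) in enumerate(region_counts):
        for k in range(cpgs_per_region):
            entries.append(("chr1", r * stride + k * spacing,
                            m // cpgs_per_region, u // cpgs_per_region))
    return make_track(entries)


class TestFisherExact:
    def test_matches_enumeration_oracle_exhaustive_small(self):
        worst = 0.0
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        err = abs(fisher_exact_p([(a, b), (c, d)])
                                  - fisher_oracle(a, b, c, d))
                        worst = max(worst, err)
        assert worst < 1e-10

    def test_matches_oracle_random_up_to_200(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 201))
            cuts = sorted(rng.integers(0, n + 1, 3))
            a, b, c = int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1])
            d = n - a - b - c
            assert fisher_exact_p([(a, b), (c, d)]) == \
                pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_balanced_table_p_one(self):
        assert fisher_exact_p([(5, 5), (5, 5)]) == pytest.approx(1.0)


class TestWindowBetas:
    def test_mean_within_window(self):
        track = make_track([("c", 10, 2, 8), ("c", 50, 4, 6)])
        out = window_betas(track, window=100)
        assert out["mean_beta"].tolist() == [pytest.approx(0.3)]

    def test_empty_windows_missing_not_zero(self):
        track = make_track([("c", 250_000, 5, 5)])
        out = window_betas(track, window=100_000)
        assert out["window_start"].tolist() == [200_000]

    def test_constant_betas(self):
        track = make_track([("c", p, 10, 0) for p in (10, 150, 250)])
        out = window_betas(track, window=100)
        assert (out["mean_beta"] == 1.0).all()


class TestConcordance:
    def test_identical_tracks(self):
        t = make_track([("c", p, m, 20 - m) for p, m in
                        [(0, 5), (10, 10), (20, 15), (30, 2)]])
        res = concordance(t, t, min_depth=20)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.discordant_fraction == 0.0
        assert res.n_cpgs == 4

    def test_anti_identity(self):
        a = make_track([("c", p, m, 20 - m) for p, m in
                        [(0, 0), (10, 5), (20, 15), (30, 20)]])
        b = make_track([("c", p, 20 - m, m) for p, m in
                        [(0, 0), (10, 5), (20, 15), (30, 20)]])
        assert concordance(a, b, min_depth=20).pearson_r == pytest.approx(-1.0)

    def test_too_few_shared_cpgs_gives_missing(self):
        a = make_track([("c", 0, 10, 10)])
        b = make_track([("c", 0, 10, 10)])
        assert np.isnan(concordance(a, b, min_depth=20).pearson_r)

    def test_min_depth_filters_both_tracks(self):
        a = make_track([("c", 0, 10, 10), ("c", 10, 30, 0)])
        b = make_track([("c", 0, 3, 2), ("c", 10, 0, 30)])
        res = concordance(a, b, min_depth=20)
        assert res.n_cpgs == 1  # only position 10 deep enough in both

    def test_binomial_resampling_high_r(self):
        rng = np.random.default_rng(41)
        betas = rng.uniform(0, 1, 1500)
        tracks = []
        for _ in range(2):
            entries = []
            for i, beta in enumerate(betas):
                m = int(rng.binomial(100, beta))
                entries.append(("c", i * 10, m, 100 - m))
            tracks.append(make_track(entries))
        res = concordance(tracks[0], tracks[1], min_depth=20)
        assert res.n_cpgs >= 1000
        assert res.pearson_r > 0.9


class TestCallDmrs:
    def test_extreme_region_emitted_at_strictest_config(self):
        a = region_track([(99, 0)])   # 33 meth per CpG x3
        b = region_track([(0, 99)])
        p_max, delta_min = DMR_CONFIGS["strict"]
        records = call_dmrs([a], [b], p_max=p_max, delta_min=delta_min)
        assert len(records) == 1
        rec = records[0]
        assert rec.delta_beta == pytest.approx(1.0)
        assert rec.p_value < 1e-7
        assert rec.p_value == pytest.approx(fisher_oracle(99, 0, 0, 99), abs=1e-10)
        assert rec.direction == "hyper"

    def test_identical_groups_no_calls(self):
        tracks = [region_track([(60, 40), (30, 70)]) for _ in range(4)]
        for p_max, delta_min in DMR_CONFIGS.values():
            assert call_dmrs(tracks[:2], tracks[2:],
                             p_max=p_max, delta_min=delta_min) == []

    def test_depth_floor_in_every_sample(self):
        deep = region_track([(50, 50)])
        shallow = region_track([(3, 3)])
        assert call_dmrs([deep, shallow], [deep, deep],
                         p_max=1.0, delta_min=0.0) == []

    def test_group_swap_antisymmetry(self):
        a = [region_track([(80, 20), (10, 90)]) for _ in range(2)]
        b = [region_track([(20, 80), (50, 50)]) for _ in range(2)]
        fwd = call_dmrs(a, b, p_max=1.0, delta_min=0.0)
        rev = call_dmrs(b, a, p_max=1.0, delta_min=0.0)
        assert len(fwd) == len(rev) == 2
        for f, r in zip(fwd, rev):
            assert f.delta_beta == pytest.approx(-r.delta_beta)
            assert f.p_value == pytest.approx(r.p_value)
            assert {f.direction, r.direction} == {"hyper", "hypo"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            call_dmrs([], [region_track([(10, 10)])])

    def test_region_span_respects_max_region(self):
        # 20 CpGs spaced 30 bp: one run of 590 bp, must be chunked <= 300 bp
        entries = [("c", 30 * k, 10, 10) for k in range(20)]
        tracks = [make_track(entries), make_track(entries)]
        records = call_dmrs([tracks[0]], [tracks[1]], p_max=1.0, delta_min=0.0)
        assert records  # identical groups pass only because thresholds are open
        for rec in records:
            assert len(rec.interval) <= 300

    def test_planted_recovery_and_specificity(self):
        # 150 null + 50 planted hyper regions, dbeta 0.6, depth ~200/sample
        rng = np.random.default_rng(43)
        n_null, n_spike = 150, 50
        betas_b = rng.uniform(0.15, 0.4, n_null + n_spike)
        betas_a = betas_b.copy()
        spiked = np.arange(n_null, n_null + n_spike)
        betas_a[spiked] += 0.6
        groups = []
        for betas in (betas_a, betas_a, betas_a, betas_b, betas_b, betas_b):
            counts = []
            for beta in betas:
                m = int(rng.binomial(198, beta))
                counts.append((m, 198 - m))
            groups.append(region_track(counts, cpgs_per_region=3))
        p_max, delta_min = DMR_CONFIGS["strict"]
        records = call_dmrs(groups[:3], groups[3:],
                            p_max=p_max, delta_min=delta_min)
        called_regions = {rec.interval.start // 500 for rec in records}
        recall = len(called_regions & set(spiked)) / n_spike
        assert recall >= 0.9
        assert not called_regions - set(spiked)

    def test_bed_output(self, tmp_path):
        records = call_dmrs([region_track([(99, 0)])], [region_track([(0, 99)])],
                            p_max=1.0, delta_min=0.0)
        path = tmp_path / "dmrs.bed"
        write_dmrs(records, path)
        fields = path.read_text().splitlines()[0].split("\t")
        assert fields[0] == "chr1" and fields[9] == "hyper"


class TestDifferentialPromoters:
    def _tss(self, n, stride=10_000):
        return ElementAnnotation("tss", [
            GenomicInterval("c", 5000 + i * stride, 5001 + i * stride, "+", f"t{i}")
            for i in range(n)])

    def _cell_tracks(self, cell_betas, n_regions, depth=300, seed=0):
        rng = np.random.default_rng(seed)
        tracks = {}
        for cell, betas in cell_betas.items():
            entries = []
            for r in range(n_regions):
                m = int(rng.binomial(depth, betas[r]))
                entries.append(("c", 5000 + r * 10_000, m, depth - m))
            tracks[cell] = make_track(entries)
        return tracks

    def test_one_vs_rest_hyper_cell_detected(self):
        n = 12
        base = [0.1] * n
        hyper = base.copy()
        hyper[3] = 0.9
        tracks = self._cell_tracks(
            {"A": hyper, "B": base, "C": base, "D": base}, n, seed=1)
        sets, summary = differential_promoters(tracks, self._tss(n))
        hyper_starts = [iv.start for iv in sets["A"]["hyper"]]
        assert 5000 + 3 * 10_000 - 4000 in hyper_starts
        assert summary["n_tested"] > 0

    def test_identical_cells_all_empty(self):
        n = 8
        tracks = self._cell_tracks({c: [0.4] * n for c in "ABC"}, n, seed=2)
        sets, _ = differential_promoters(tracks, self._tss(n))
        assert all(not sets[c]["hyper"] and not sets[c]["hypo"] for c in "ABC")

    def test_bh_qvalues_monotone_in_sorted_p(self):
        pvals = [0.001, 0.01, 0.02, 0.2, 0.9]
        from statsmodels.stats.multitest import multipletests
        q = multipletests(pvals, method="fdr_bh")[1]
        assert all(q1 <= q2 for q1, q2 in zip(q, q[1:]))

    def test_requires_two_cells(self):
        with pytest.raises(ValueError):
            differential_promoters({"A": make_track([])}, self._tss(1))


class TestPeakAssociation:
    def _regions(self, starts, chrom="c"):
        return [GenomicInterval(chrom, int(s), int(s) + 200) for s in starts]

    def test_known_table_matches_oracle(self):
        # geometry realizing the table [[8,2],[1,9]] for cell1's peak set
        hypo = {"cell1": self._regions(range(0, 10_000, 1000)),
                "cell2": self._regions(range(100_000, 110_000, 1000))}
        peaks = {
            "cell1": self._regions(list(range(0, 8000, 1000)) + [100_000]),
            "cell2": self._regions([100_000]),
        }
        res = peak_association(hypo, peaks)
        assert res.tables["cell1"].tolist() == [[8, 2], [1, 9]]
        assert res.row_percentages["cell1"]["cell1"] == pytest.approx(80.0)
        assert res.p_values["cell1"] == \
            pytest.approx(fisher_oracle(8, 2, 1, 9), abs=1e-10)

    def test_no_association_p_one(self):
        # cell1's peaks cover half of each region set: table [[5,5],[5,5]]
        hypo = {"c1": self._regions(range(0, 10_000, 1000)),
                "c2": self._regions(range(100_000, 110_000, 1000))}
        peaks = {"c1": self._regions(list(range(0, 5000, 1000))
                                     + list(range(100_000, 105_000, 1000))),
                 "c2": self._regions([])}
        res = peak_association(hypo, peaks)
        assert res.tables["c1"].tolist() == [[5, 5], [5, 5]]
        assert res.p_values["c1"] == pytest.approx(1.0)

    def test_empty_region_set_p_missing(self):
        hypo = {"c1": [], "c2": self._regions([0])}
        peaks = {"c1": [], "c2": []}
        res = peak_association(hypo, peaks)
        assert np.isnan(res.p_values["c1"]) and np.isnan(res.p_values["c2"])

    def test_planted_colocation_significant(self):
        rng = np.random.default_rng(44)
        starts1 = rng.choice(10_000, 15, replace=False) * 100
        starts2 = rng.choice(10_000, 15, replace=False) * 100 + 2_000_000
        hypo = {"c1": self._regions(starts1), "c2": self._regions(starts2)}
        peaks = {"c1": self._regions(starts1[:14]),   # peaks sit on own hypo regions
                 "c2": self._regions(starts2[:14])}
        res = peak_association(hypo, peaks)
        assert res.p_values["c1"] < 0.01 and res.p_values["c2"] < 0.01
        assert res.own_peak_percentages["c1"] > 90.0
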