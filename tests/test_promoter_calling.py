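"""Promoter definition: local maxima, annotation filter, fixed-window
collection, spread statistics and the distance-clustering baseline."""

import numpy as np
import pandas as pd
import pytest

from cageprom.cage_io import BED_COLUMNS, TagLandscape
from cageprom import promoter_calling as pc
from cageprom import synthetic_data as sd


def _landscape(site_counts, strand="+", sample="a", contig="chr1"):
    recs = [(contig, pos, strand, sample, c) for pos, c in site_counts.items()]
    return TagLandscape.from_records(recs, [sample])


def exhaustive_local_maxima(site_counts, d, strand="+"):
    """Oracle: literal scan over all sites."""
    out = []
    items = sorted(site_counts.items())
    for pos, c in items:
        if c <= 0:
            continue
        neighbors = [(p, n) for p, n in items if p != pos and abs(p - pos) <= d]
        if any(n > c for _, n in neighbors):
            continue
        tied = [p for p, n in neighbors if n == c]
        five_prime = (lambda a, b: a < b) if strand == "+" else (lambda a, b: a > b)
        if any(five_prime(p, pos) for p in tied):
            continue
        out.append(pos)
    return sorted(out)


class TestLocalMaxima:
    def test_single_site(self):
        land = _landscape({100: 5})
        assert pc.find_local_maxima(land, 50) == [("chr1", 100, "+")]

    @pytest.mark.parametrize("strand,expect", [("+", 100), ("-", 110)])
    def test_tie_keeps_five_prime_site(self, strand, expect):
        land = _landscape({100: 5, 110: 5}, strand=strand)
        assert pc.find_local_maxima(land, 50) == [("chr1", expect, strand)]

    def test_double_peak_depends_on_d(self):
        counts = {100: 8, 105: 3, 130: 9}
        land = _landscape(counts)
        got20 = [a[1] for a in pc.find_local_maxima(land, 20)]
        got50 = [a[1] for a in pc.find_local_maxima(land, 50)]
        assert got20 == exhaustive_local_maxima(counts, 20) == [100, 130]
        assert got50 == exhaustive_local_maxima(counts, 50) == [130]

    def test_matches_exhaustive_oracle_on_random_landscapes(self, rng):
        for _ in range(25):
            n = rng.integers(3, 30)
            pos = rng.choice(500, size=n, replace=False)
            counts = dict(zip(pos.tolist(), rng.integers(0, 8, size=n).tolist()))
            for strand in "+-":
                land = _landscape(counts, strand=strand)
                got = [a[1] for a in pc.find_local_maxima(land, 25)]
                assert got == exhaustive_local_maxima(counts, 25, strand)

    def test_no_two_anchors_within_d(self, small_cohort):
        anchors = pc.find_local_maxima(small_cohort.landscape, 50)
        by_key = {}
        for c, p, s in anchors:
            by_key.setdefault((c, s), []).append(p)
        for ps in by_key.values():
            ps = sorted(ps)
            assert all(b - a > 50 for a, b in zip(ps, ps[1:]))


class TestAnnotationFilter:
    def _bed(self, rows):
        return pd.DataFrame(rows, columns=BED_COLUMNS)

    def test_boundary_inclusive(self):
        bed = self._bed([("chr1", 149, 150, "t", 0.0, "+")])
        kept = pc.filter_by_annotation([("chr1", 100, "+")], bed, 50)
        assert kept == [("chr1", 100, "+")]

    def test_beyond_d_discarded(self):
        bed = self._bed([("chr1", 151, 152, "t", 0.0, "+")])
        assert pc.filter_by_annotation([("chr1", 100, "+")], bed, 50) == []

    def test_opposite_strand_tss_does_not_rescue(self):
        bed = self._bed([("chr1", 100, 101, "t", 0.0, "-")])
        assert pc.filter_by_annotation([("chr1", 100, "+")], bed, 50) == []

    def test_minus_strand_tss_is_bed_end_minus_one(self):
        bed = self._bed([("chr1", 100, 200, "t", 0.0, "-")])
        kept = pc.filter_by_annotation([("chr1", 240, "-")], bed, 50)
        assert kept == [("chr1", 240, "-")]  # |240 - 199| <= 50


class TestCollect:
    def test_all_tags_inside_window_collected(self):
        land = _landscape({95: 2, 100: 5, 140: 3})
        (p,) = pc.collect_promoters([("chr1", 100, "+")], land, 50)
        assert p.tag_count == 10
        assert p.offsets.sum() == p.per_sample_counts.sum() == 10

    def test_equidistant_tag_goes_to_five_prime_anchor_only(self):
        land = _landscape({100: 1, 140: 6, 180: 1})
        proms = pc.collect_promoters(
            [("chr1", 100, "+"), ("chr1", 180, "+")], land, 50
        )
        by_anchor = {p.anchor: p.tag_count for p in proms}
        # the tag at 140 is 40 from both anchors -> 5' anchor (100)
        assert by_anchor == {100: 7, 180: 1}
        assert sum(by_anchor.values()) == 8  # conservation, no double count

    def test_cohort_promoter_count_matches_planted_truth(self, small_cohort):
        proms = pc.collect_promoters(
            pc.filter_by_annotation(
                pc.find_local_maxima(small_cohort.landscape, 50),
                small_cohort.tss_bed,
                50,
            ),
            small_cohort.landscape,
            50,
        )
        assert len(proms) == len(small_cohort.truths)
        for p in proms:
            assert any(
                t.contig == p.contig
                and t.strand == p.strand
                and abs(t.anchor - p.anchor) <= 50
                for t in small_cohort.truths
            )


class TestSpread:
    def test_single_site_zero_spread(self):
        s = pc.tss_spread(positions=np.array([42]), weights=np.array([9]))
        assert s.iqr == 0.0 and s.sd == 0.0

    def test_hand_computed_quartiles_and_sd(self):
        s = pc.tss_spread(
            positions=np.array([0, 1, 2, 3]), weights=np.array([1, 1, 1, 1])
        )
        assert s.iqr == pytest.approx(1.5)
        assert s.sd == pytest.approx(np.sqrt(5) / 2)

    def test_weighted_quantile_equals_expanded_multiset(self, rng):
        for _ in range(50):
            vals = rng.integers(-30, 30, size=rng.integers(1, 12))
            w = rng.integers(1, 6, size=len(vals))
            expanded = np.repeat(vals, w)
            for q in (0.25, 0.5, 0.75):
                assert pc.weighted_quantile(vals, w, q) == pytest.approx(
                    np.quantile(expanded, q)
                )

    def test_zero_tags_is_an_error(self):
        with pytest.raises(ValueError, match="zero tags"):
            pc.tss_spread(positions=np.array([1]), weights=np.array([0]))

    def test_profile_classes_match_expected_scales(self, rng):
        # generator calibration: narrow IQR near 2, broad near 20
        for shape, lo, hi in [("narrow", 1.0, 4.0), ("broad", 15.0, 25.0)]:
            profile = sd.initiation_profile(shape, 50)
            iqrs = []
            for _ in range(50):
                w = rng.multinomial(500, profile)
                iqrs.append(
                    pc.tss_spread(positions=np.arange(-50, 51), weights=w).iqr
                )
            assert lo <= np.median(iqrs) <= hi


class TestDistanceCluster:
    def test_gap_linkage(self):
        cl = pc.distance_cluster(positions=np.array([10, 25, 100]), gap=20)
        assert [(c.start, c.end) for c in cl] == [(10, 25), (100, 100)]

    def test_empty_landscape(self):
        land = TagLandscape.from_records([], ["a"])
        assert pc.distance_cluster(land, gap=20) == []

    def test_cluster_width_grows_with_depth_but_iqr_stable(self):
        off = np.arange(-200, 201)
        tail = 0.95 ** np.abs(off)
        profile = 0.8 * sd.initiation_profile("broad", 200) + 0.2 * tail / tail.sum()
        df = pc.depth_artifact_experiment(
            profile, depths=(100, 10_000), n_reps=100, gap=20, d=50, seed=3
        )
        med = df.groupby("depth")[["mean_cluster_width", "fixed_window_iqr"]].median()
        # the artifact: distance clusters widen substantially with depth
        assert med.loc[10_000, "mean_cluster_width"] > 1.2 * med.loc[
            100, "mean_cluster_width"
        ]
        # fixed-window IQR is depth-stable within the Monte-Carlo band
        shallow = df[df.depth == 100]["fixed_window_iqr"]
        deep = df[df.depth == 10_000]["fixed_window_iqr"]
        band = 2 * shallow.std() / np.sqrt(len(shallow))
        assert abs(shallow.median() - deep.median()) <= max(band, 1.0)

    def test_double_peak_profile_clusters_depend_on_depth_not_shape(self):
        # identical double-peak truth sampled at 40 vs 4000 tags: gap-20
        # clustering splits the shallow but merges the deep sample, while
        # fixed-window offset histograms keep the same shape
        from scipy.stats import chi2_contingency

        off = np.arange(-100, 101)
        p = 0.85 ** np.abs(off + 30) + 0.85 ** np.abs(off - 30)
        p = p / p.sum()
        rng = np.random.default_rng(0)
        shallow = rng.multinomial(40, p)
        deep = rng.multinomial(4000, p)
        n_shallow = len(
            pc.distance_cluster(
                positions=off[shallow > 0], counts=shallow[shallow > 0], gap=20
            )
        )
        n_deep = len(
            pc.distance_cluster(
                positions=off[deep > 0], counts=deep[deep > 0], gap=20
            )
        )
        assert n_shallow > n_deep  # more tags -> wider, merged clusters
        w = np.abs(off) <= 50
        bins = np.arange(-50, 61, 20)
        hs, _ = np.histogram(off[w], bins=bins, weights=shallow[w])
        hd, _ = np.histogram(off[w], bins=bins, weights=deep[w])
        keep = (hs + hd) > 0
        res = chi2_contingency(np.vstack([hs[keep], hd[keep]]))
        assert res.pvalue > 0.01  # same normalized shape in the fixed window
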