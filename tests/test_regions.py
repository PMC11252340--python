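"""Interval engine: worked examples plus per-base boolean oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rejuvenome.regions import (RegionSet, annotate_regions, build_background,
                                consensus_peaks, cpg_shores_shelves,
                                define_bivalent, define_promoters,
                                detect_switch_domains, intersect_regions,
                                merge_regions, subtract_regions,
                                switch_methylation_trend)

SIZES = {"chr1": 10_000, "chr2": 10_000}


def coverage(rs: RegionSet, size: int = 10_000) -> dict:
    """Per-base boolean membership arrays, the brute-force oracle."""
    cov = {c: np.zeros(size, dtype=bool) for c in SIZES}
    for c, s, e in rs.df[["chrom", "start", "end"]].itertuples(index=False):
        cov[c][s:e] = True
    return cov


def random_set(rng, n_max=20) -> RegionSet:
    n = rng.integers(1, n_max + 1)
    chroms = rng.choice(list(SIZES), size=n)
    starts = rng.integers(0, 9_000, size=n)
    lengths = rng.integers(1, 1_000, size=n)
    return RegionSet.from_tuples(
        [(c, int(s), int(min(s + l, 10_000)))
         for c, s, l in zip(chroms, starts, lengths)], SIZES)


class TestMergeIntersect:
    def test_merge_example(self):
        rs = RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 5, 15),
                                    ("chr1", 20, 30)])
        out = merge_regions(rs)
        assert list(out.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(0, 15), (20, 30)]

    def test_merge_disjoint_identity(self):
        rs = RegionSet.from_tuples([("chr1", 20, 30), ("chr1", 0, 10)])
        out = merge_regions(rs)
        assert list(out.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(0, 10), (20, 30)]

    def test_intersect_example(self):
        a = RegionSet.from_tuples([("chr1", 100, 200)])
        b = RegionSet.from_tuples([("chr1", 150, 300)])
        out, pairs = intersect_regions(a, b)
        assert list(out.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(150, 200)]
        assert pairs == [(0, 0)]

    def test_intersect_disjoint_empty(self):
        a = RegionSet.from_tuples([("chr1", 0, 10)])
        b = RegionSet.from_tuples([("chr1", 50, 60)])
        out, pairs = intersect_regions(a, b)
        assert len(out) == 0 and pairs == []

    def test_merge_matches_per_base_oracle(self, rng):
        for _ in range(100):
            rs = random_set(rng)
            merged = merge_regions(rs)
            assert all(np.array_equal(coverage(rs)[c], coverage(merged)[c])
                       for c in SIZES)
            # disjoint and sorted
            for _, g in merged.df.groupby("chrom"):
                assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_intersect_matches_per_base_and_commutes(self, rng):
        for _ in range(100):
            a, b = random_set(rng), random_set(rng)
            ab, _ = intersect_regions(a, b)
            ba, _ = intersect_regions(b, a)
            for c in SIZES:
                want = coverage(a)[c] & coverage(b)[c]
                assert np.array_equal(coverage(ab)[c], want)
                assert np.array_equal(coverage(ba)[c], want)

    def test_subtract_matches_per_base_oracle(self, rng):
        for _ in range(50):
            a, b = random_set(rng), random_set(rng)
            out = subtract_regions(a, b)
            for c in SIZES:
                assert np.array_equal(coverage(out)[c],
                                      coverage(a)[c] & ~coverage(b)[c])

    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 99)),
                    min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_merge_idempotent(self, items):
        rs = RegionSet.from_tuples([("chr1", s, s + l) for s, l in items])
        once = merge_regions(rs)
        assert merge_regions(once) == once

    def test_consensus_is_merge_of_concat(self, rng):
        sets = [random_set(rng) for _ in range(3)]
        cons = consensus_peaks(sets)
        concat = RegionSet(pd.concat([s.df for s in sets], ignore_index=True), SIZES)
        assert cons == merge_regions(concat)

    def test_consensus_idempotent_on_identical_sets(self):
        a = RegionSet.from_tuples([("chr1", 0, 10), ("chr1", 30, 40)])
        assert consensus_peaks([a, a]) == merge_regions(a)
        assert consensus_peaks([RegionSet.from_tuples([("chr1", 0, 10)]),
                                RegionSet.from_tuples([("chr1", 8, 20)])]) \
            == RegionSet.from_tuples([("chr1", 0, 20)])

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            RegionSet.from_tuples([("chrX", 0, 10)], SIZES)


class TestPromoters:
    GENES = RegionSet.from_tuples(
        [("chr1", 5000, 8000, "gA", 0, "+"), ("chr1", 5000, 8000, "gB", 0, "-")],
        SIZES)

    def test_plus_strand(self):
        plus = RegionSet.from_tuples([("chr1", 5000, 8000, "gA", 0, "+")], SIZES)
        out = define_promoters(plus)
        assert tuple(out.df.iloc[0][["start", "end"]]) == (4000, 5100)

    def test_minus_strand_mirror(self):
        minus = RegionSet.from_tuples([("chr1", 5000, 8000, "gB", 0, "-")], SIZES)
        out = define_promoters(minus)
        assert tuple(out.df.iloc[0][["start", "end"]]) == (7900, 9000)

    def test_clipping_at_chromosome_start(self):
        g = RegionSet.from_tuples([("chr1", 500, 2000, "g", 0, "+")], SIZES)
        out = define_promoters(g, up=1000, down=100)
        assert tuple(out.df.iloc[0][["start", "end"]]) == (0, 600)

    def test_dot_strand_rejected(self):
        g = RegionSet.from_tuples([("chr1", 500, 2000, "g", 0, ".")], SIZES)
        with pytest.raises(ValueError, match="strand"):
            define_promoters(g)

    def test_strand_mirror_symmetry(self, rng):
        """Reversing the genome maps + promoters onto - promoters."""
        L = SIZES["chr1"]
        for _ in range(20):
            s = int(rng.integers(1500, 8000))
            e = int(s + rng.integers(100, 1000))
            fwd = define_promoters(
                RegionSet.from_tuples([("chr1", s, e, "g", 0, "+")], SIZES))
            rev = define_promoters(
                RegionSet.from_tuples([("chr1", L - e, L - s, "g", 0, "-")], SIZES))
            fs, fe = fwd.df.iloc[0][["start", "end"]]
            rs_, re_ = rev.df.iloc[0][["start", "end"]]
            assert (L - re_, L - rs_) == (fs, fe)


class TestCpgContext:
    def test_shores_example(self):
        isl = RegionSet.from_tuples([("chr1", 10000, 11000)],
                                    {"chr1": 50_000})
        shores, shelves = cpg_shores_shelves(isl)
        assert list(shores.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(8000, 10000), (11000, 13000)]
        assert list(shelves.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(6000, 8000), (13000, 15000)]

    def test_close_islands_disjoint_classes(self):
        isl = RegionSet.from_tuples([("chr1", 10000, 11000), ("chr1", 12000, 12500)],
                                    {"chr1": 50_000})
        shores, shelves = cpg_shores_shelves(isl)
        ci = coverage(isl, 50_000)["chr1"]
        cs = np.zeros(50_000, bool)
        for c, s, e in shores.df[["chrom", "start", "end"]].itertuples(index=False):
            cs[s:e] = True
        cv = np.zeros(50_000, bool)
        for c, s, e in shelves.df[["chrom", "start", "end"]].itertuples(index=False):
            cv[s:e] = True
        assert not (ci & cs).any() and not (ci & cv).any() and not (cs & cv).any()

    def test_classes_tile_without_overlap_random(self, rng):
        for _ in range(30):
            isl = random_set(rng, n_max=6)
            shores, shelves = cpg_shores_shelves(isl)
            for c in SIZES:
                ci = coverage(merge_regions(isl))[c]
                cs = coverage(shores)[c]
                cv = coverage(shelves)[c]
                assert not (ci & cs).any()
                assert not ((ci | cs) & cv).any()
                # shores+shelves together are exactly the 4 kb flank minus islands
                want = np.zeros(SIZES[c], bool)
                for cc, s, e in merge_regions(isl).df[
                        ["chrom", "start", "end"]].itertuples(index=False):
                    if cc == c:
                        want[max(0, s - 4000):s] = True
                        want[e:e + 4000] = True
                want &= ~ci
                assert np.array_equal(cs | cv, want)


class TestBackground:
    def test_unmasked_bins(self):
        bg = build_background({"chr1": 1000}, None, bin=200)
        assert len(bg) == 5 and bg.total_bases() == 1000

    def test_masked_bins_avoid_mask_and_conserve_bases(self):
        mask = RegionSet.from_tuples([("chr1", 400, 600)])
        bg = build_background({"chr1": 1000}, mask, bin=200)
        assert bg.total_bases() == 800
        for _, s, e in bg.df[["chrom", "start", "end"]].itertuples(index=False):
            assert e <= 400 or s >= 600

    def test_base_conservation_random_masks(self, rng):
        for _ in range(20):
            mask = random_set(rng, n_max=8)
            bg = build_background(SIZES, mask, bin=200)
            masked = merge_regions(mask).total_bases()
            assert bg.total_bases() == sum(SIZES.values()) - masked
            assert (bg.df["end"] - bg.df["start"] <= 200).all()


class TestAnnotation:
    GENES = RegionSet.from_tuples(
        [("chr1", 3000, 6000, "gA", 0, "+"), ("chr2", 4000, 7000, "gB", 0, "-")],
        SIZES)
    ISLANDS = RegionSet.from_tuples([("chr1", 2800, 3200, "cgi0")], SIZES)

    def test_promoter_precedence_over_gene_body(self):
        # region inside gA's promoter [2000,3100) and its gene body
        r = RegionSet.from_tuples([("chr1", 3050, 3080, "r0")], SIZES)
        lab = annotate_regions(r, self.GENES, self.ISLANDS)
        assert lab.loc[0, "gene_context"] == "promoter"
        assert lab.loc[0, "cpg_context"] == "island"
        assert lab.loc[0, "nearest_gene"] == "gA"

    def test_intergenic_open_sea(self):
        r = RegionSet.from_tuples([("chr1", 9000, 9100, "r0")], SIZES)
        lab = annotate_regions(r, self.GENES, self.ISLANDS)
        assert lab.loc[0, "gene_context"] == "intergenic"
        assert lab.loc[0, "cpg_context"] == "open_sea"

    def test_every_region_gets_exactly_one_label_per_category(self, rng):
        r = random_set(rng, n_max=30)
        lab = annotate_regions(r, self.GENES, self.ISLANDS)
        assert len(lab) == len(r)
        assert lab["gene_context"].isin(
            ["promoter", "distal_promoter", "gene_body", "intergenic"]).all()
        assert lab["cpg_context"].isin(
            ["island", "shore", "shelf", "open_sea"]).all()

    def test_matches_brute_force_scan(self, rng):
        from rejuvenome.regions import define_distal_promoters
        proms = define_promoters(self.GENES)
        distal = define_distal_promoters(self.GENES)
        shores, shelves = cpg_shores_shelves(self.ISLANDS)
        for _ in range(30):
            r = random_set(rng, n_max=10)
            lab = annotate_regions(r, self.GENES, self.ISLANDS)
            for i, (c, s, e) in enumerate(
                    r.df[["chrom", "start", "end"]].itertuples(index=False)):
                def hits(track):
                    return any(tc == c and ts < e and te > s for tc, ts, te in
                               track.df[["chrom", "start", "end"]]
                               .itertuples(index=False))
                if hits(proms):
                    want = "promoter"
                elif hits(distal):
                    want = "distal_promoter"
                elif hits(self.GENES):
                    want = "gene_body"
                else:
                    want = "intergenic"
                assert lab.loc[i, "gene_context"] == want
                if hits(self.ISLANDS):
                    wantc = "island"
                elif hits(shores):
                    wantc = "shore"
                elif hits(shelves):
                    wantc = "shelf"
                else:
                    wantc = "open_sea"
                assert lab.loc[i, "cpg_context"] == wantc


class TestDomains:
    def test_bivalent_intersection(self):
        k4 = RegionSet.from_tuples([("chr1", 100, 200)])
        k27 = RegionSet.from_tuples([("chr1", 150, 300)])
        out = define_bivalent(k4, k27)
        assert list(out.df[["start", "end"]].itertuples(index=False, name=None)) \
            == [(150, 200)]
        assert len(define_bivalent(k4, RegionSet.from_tuples([("chr1", 500, 600)]))) == 0

    def test_switch_domain_example(self):
        k27 = RegionSet.from_tuples([("chr1", 1000, 2000, "a|up")])
        k9 = RegionSet.from_tuples([("chr1", 1500, 3000, "b|down")])
        domains, summary = detect_switch_domains(k27, k9)
        assert summary == {"count": 1, "mean_length_bp": 500.0}
        d = domains[0]
        assert (d.chrom, d.start, d.end) == ("chr1", 1500, 2000)
        assert d.k27_der_ids == ["a"] and d.k9_der_ids == ["b"]

    def test_direction_filter_excludes_down_in_down(self):
        k27 = RegionSet.from_tuples([("chr1", 1500, 2000, "a|down")])
        k9 = RegionSet.from_tuples([("chr1", 1000, 3000, "b|down")])
        domains, summary = detect_switch_domains(k27, k9)
        assert summary["count"] == 0 and domains == []

    def test_missing_direction_labels_rejected(self):
        k27 = RegionSet.from_tuples([("chr1", 1000, 2000, "a")])
        k9 = RegionSet.from_tuples([("chr1", 1500, 3000, "b|down")])
        with pytest.raises(ValueError, match="direction"):
            detect_switch_domains(k27, k9)

    def test_methylation_trend_examples(self):
        frac, excl = switch_methylation_trend([0.55, 0.60, 0.70], [0.50, 0.55, 0.65])
        assert frac == 1.0 and excl == 0
        frac, excl = switch_methylation_trend([0.5, np.nan], [0.5, 0.4])
        assert frac == 0.0 and excl == 1  # tie counts as not increased

    def test_methylation_trend_null_symmetric(self, rng):
        diffs = rng.normal(0, 0.01, size=2000)
        base = rng.uniform(0.4, 0.9, size=2000)
        frac, _ = switch_methylation_trend(base + diffs, base)
        assert abs(frac - 0.5) < 0.05
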