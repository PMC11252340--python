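"""Intersection-testing machinery: permutation and Fisher enrichment.

Two permutation schemes are provided for genomic regions — free
randomization over a masked background of equivalent-length regions, and
resampling from a fixed universe of regions — plus an equal-size resampling
test for gene sets.  All report an empirical one-sided (over-enrichment)
p-value with the +1 small-sample correction,

    p = (1 + #{null >= observed}) / (1 + n_perm),

and a fold enrichment observed / mean(null) (denominator floored at
1/n_perm so an empty null cannot divide by zero).  One-sided Fisher exact
tests and Benjamini-Hochberg adjustment complete the battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust  # noqa: F401  (re-exported battery helper)
from .regions import RegionSet, merge_regions


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    n_perm: int
    empirical_p: float
    fold_enrichment: float
    seed: int
    comparison: str = ""
    padj: float | None = None

    def to_row(self) -> dict:
        return {"comparison": self.comparison, "observed": self.observed,
                "null_mean": self.null_mean, "null_sd": self.null_sd,
                "n_perm": self.n_perm, "empirical_p": self.empirical_p,
                "fold_enrichment": self.fold_enrichment, "padj": self.padj,
                "seed": self.seed}


def _summarize(observed: int, null: np.ndarray, n_perm: int, seed: int,
               comparison: str) -> EnrichmentResult:
    null = np.asarray(null, dtype=float)
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    fe = observed / max(float(null.mean()), 1.0 / n_perm)
    return EnrichmentResult(int(observed), float(null.mean()), float(null.std(ddof=0)),
                            int(n_perm), float(p), float(fe), int(seed), comparison)


# ---------------------------------------------------------------------------
# Region overlap statistic and randomization
# ---------------------------------------------------------------------------

def overlap_statistic(a: RegionSet, b: RegionSet) -> int:
    """Number of regions of `a` overlapping >=1 region of `b` (>=1 shared base)."""
    if len(a) == 0 or len(b) == 0:
        return 0
    bm = merge_regions(b).by_chrom()
    total = 0
    for chrom, sub in a.df.groupby("chrom", sort=False):
        if chrom not in bm:
            continue
        b_s, b_e = bm[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        idx = np.searchsorted(b_e, s, side="right")
        hit = (idx < len(b_s)) & (b_s[np.minimum(idx, len(b_s) - 1)] < e)
        total += int(hit.sum())
    return total


def _overlap_counts_vectorized(starts: np.ndarray, ends: np.ndarray,
                               chrom_idx: np.ndarray,
                               b_by_idx: list[tuple[np.ndarray, np.ndarray]]) -> int:
    total = 0
    for ci, (b_s, b_e) in enumerate(b_by_idx):
        m = chrom_idx == ci
        if not m.any() or len(b_s) == 0:
            continue
        s, e = starts[m], ends[m]
        idx = np.searchsorted(b_e, s, side="right")
        hit = (idx < len(b_s)) & (b_s[np.minimum(idx, len(b_s) - 1)] < e)
        total += int(hit.sum())
    return total


class _Background:
    """Flattened valid-start bookkeeping for length-preserving randomization.

    Each placement of a region of length L is uniform over all start
    positions, across segments, for which [start, start+L) fits inside a
    single background segment — i.e. segments are chosen with probability
    proportional to their count of valid starts.
    """

    def __init__(self, background: RegionSet):
        bg = merge_regions(background)
        self.chroms = bg.df["chrom"].to_numpy()
        self.starts = bg.df["start"].to_numpy()
        self.ends = bg.df["end"].to_numpy()
        self.lengths = self.ends - self.starts

    def sample_starts(self, rng: np.random.Generator, L: int, size: int
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(chrom index into self.chroms, start) for `size` placements."""
        valid = np.maximum(0, self.lengths - L + 1)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(
                f"region of length {L} bp is longer than every background segment")
        flat = rng.integers(0, total, size=size)
        cum = np.cumsum(valid)
        seg = np.searchsorted(cum, flat, side="right")
        offs = flat - (cum[seg] - valid[seg])
        return seg, self.starts[seg] + offs


def randomize_regions(a: RegionSet, background: RegionSet, n_perm: int = 1000,
                      seed: int = 0) -> list[RegionSet]:
    """Length-preserving random placements of `a` over the background.

    Placed regions may overlap each other; every placement lies wholly
    inside a background segment.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    bg = _Background(background)
    lengths = (a.df["end"] - a.df["start"]).to_numpy()
    out = []
    for _ in range(n_perm):
        rows = []
        for L in lengths:
            seg, start = bg.sample_starts(rng, int(L), 1)
            rows.append((bg.chroms[seg[0]], int(start[0]), int(start[0]) + int(L)))
        out.append(RegionSet.from_tuples(rows))
    return out


def permutation_region_test(a: RegionSet, b: RegionSet, background: RegionSet,
                            n_perm: int = 1000, seed: int = 0,
                            comparison: str = "") -> EnrichmentResult:
    """One-sided over-enrichment test of the a/b overlap against random
    length-matched placements of `a` over the background."""
    rng = np.random.default_rng(seed)
    observed = overlap_statistic(a, b)
    bg = _Background(background)
    lengths = (a.df["end"] - a.df["start"]).to_numpy()
    chrom_list = sorted(set(bg.chroms))
    chrom_lut = {c: i for i, c in enumerate(chrom_list)}
    bm = merge_regions(b).by_chrom()
    b_by_idx = [bm.get(c, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
                for c in chrom_list]
    seg_chrom_idx = np.array([chrom_lut[c] for c in bg.chroms])
    null = np.empty(n_perm)
    for k in range(n_perm):
        starts = np.empty(len(lengths), dtype=np.int64)
        cidx = np.empty(len(lengths), dtype=np.int64)
        # group identical lengths to vectorize the draw
        for L in np.unique(lengths):
            m = lengths == L
            seg, st = bg.sample_starts(rng, int(L), int(m.sum()))
            starts[m] = st
            cidx[m] = seg_chrom_idx[seg]
        null[k] = _overlap_counts_vectorized(starts, starts + lengths, cidx, b_by_idx)
    return _summarize(observed, null, n_perm, seed, comparison)


def resample_region_test(a: RegionSet, b: RegionSet, universe: RegionSet,
                         n_perm: int = 1000, seed: int = 0,
                         comparison: str = "") -> EnrichmentResult:
    """Over-enrichment of the a/b overlap against equal-size draws of
    universe members (without replacement).  `a` must be a subset of the
    universe by coordinate identity."""
    rng = np.random.default_rng(seed)
    key = lambda df: set(map(tuple, df[["chrom", "start", "end"]].to_numpy()))
    if not key(a.df) <= key(universe.df):
        raise ValueError("a is not a subset of the universe")
    if len(universe) < len(a):
        raise ValueError("universe smaller than a")
    observed = overlap_statistic(a, b)
    u_s = universe.df["start"].to_numpy()
    u_e = universe.df["end"].to_numpy()
    chrom_list = sorted(universe.df["chrom"].unique())
    chrom_lut = {c: i for i, c in enumerate(chrom_list)}
    u_c = universe.df["chrom"].map(chrom_lut).to_numpy()
    bm = merge_regions(b).by_chrom()
    b_by_idx = [bm.get(c, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)))
                for c in chrom_list]
    null = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(len(universe), size=len(a), replace=False)
        null[k] = _overlap_counts_vectorized(u_s[pick], u_e[pick], u_c[pick], b_by_idx)
    return _summarize(observed, null, n_perm, seed, comparison)


def permutation_gene_test(set_a, set_b, universe, n_perm: int = 1000,
                          seed: int = 0, comparison: str = "") -> EnrichmentResult:
    """Over-enrichment of |A intersect B| against equal-size random draws of A
    from the universe (B held fixed)."""
    rng = np.random.default_rng(seed)
    set_a, set_b, universe = set(set_a), set(set_b), list(dict.fromkeys(universe))
    uset = set(universe)
    if not (set_a <= uset and set_b <= uset):
        raise ValueError("gene sets must be contained in the universe")
    observed = len(set_a & set_b)
    uni = np.array(sorted(universe))
    in_b = np.isin(uni, sorted(set_b))
    null = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(len(uni), size=len(set_a), replace=False)
        null[k] = int(in_b[pick].sum())
    return _summarize(observed, null, n_perm, seed, comparison)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_overlap(k: int, a_only: int, b_only: int, neither: int
                   ) -> tuple[float, float]:
    """One-sided (over-enrichment) Fisher exact test of a 2x2 overlap table.

    Returns (odds ratio, p).  The odds ratio is the sample odds ratio, with
    the Haldane 0.5 continuity correction applied iff any cell is zero; p is
    the upper hypergeometric tail P(X >= k).
    """
    cells = np.array([k, a_only, b_only, neither], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if cells.sum() == 0:
        raise ValueError("all-zero contingency table")
    if (cells == 0).any():
        cells = cells + 0.5
    orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    p = float(stats.fisher_exact([[k, a_only], [b_only, neither]],
                                 alternative="greater")[1])
    return float(orr), p


def enrichment_table(results: list[EnrichmentResult], family: str = "") -> pd.DataFrame:
    """Collect results, BH-adjust within the family, return the TSV table."""
    df = pd.DataFrame([r.to_row() for r in results])
    if len(df):
        df["padj"] = bh_adjust(df["empirical_p"].to_numpy(), family)
        for r, adj in zip(results, df["padj"]):
            r.padj = float(adj)
    return df
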