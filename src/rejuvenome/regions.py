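"""Genomic interval engine.

All coordinates are 0-based, half-open ([start, end)), matching BED
semantics.  A :class:`RegionSet` is a thin, immutable-by-convention wrapper
around a sorted :class:`pandas.DataFrame` with columns ``chrom``, ``start``,
``end`` and optional ``name``, ``score``, ``strand``.  It is the currency of
all interval logic in the package: peak combination, promoter/CpG-context
annotation, background construction, and the bivalent and
heterochromatin-switch domain definitions.

The overlap predicate everywhere is "shares at least one base"; no
minimum-fraction rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class RegionSet:
    """Sorted set of genomic intervals (0-based, half-open).

    Parameters
    ----------
    df
        DataFrame with at least ``chrom``, ``start``, ``end``; optional
        ``name``, ``score``, ``strand``. Rows are sorted by
        (chrom, start, end) on construction.
    chrom_sizes
        Optional mapping chrom -> length used to validate bounds.
    """

    def __init__(self, df: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"RegionSet requires a '{col}' column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval has start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if chrom_sizes is not None:
            unknown = set(df["chrom"]) - set(chrom_sizes)
            if unknown:
                raise ValueError(f"unknown chromosome(s): {sorted(unknown)}")
            ends = df["chrom"].map(chrom_sizes)
            if (df["end"] > ends).any():
                raise ValueError("interval extends beyond chromosome bounds")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None

    # -- convenience -------------------------------------------------------
    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[tuple],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "RegionSet":
        """Build from (chrom, start, end[, name[, score[, strand]]]) tuples."""
        rows = [list(t) for t in tuples]
        ncol = max((len(r) for r in rows), default=3)
        cols = _BED_COLS[:ncol]
        df = pd.DataFrame([r + [None] * (ncol - len(r)) for r in rows], columns=cols)
        return cls(df, chrom_sizes)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out


# ---------------------------------------------------------------------------
# Core algebra
# ---------------------------------------------------------------------------

def merge_regions(regions: RegionSet) -> RegionSet:
    """Union of overlapping (or book-ended only if sharing a base: they are
    NOT merged when merely adjacent) intervals.

    Output is sorted and pairwise disjoint; the covered base set is identical
    to the input's union.
    """
    rows = []
    for chrom, (starts, ends) in regions.by_chrom().items():
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # shares >=1 base
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return RegionSet.from_tuples(rows, regions.chrom_sizes)


def intersect_regions(a: RegionSet, b: RegionSet) -> tuple[RegionSet, list[tuple[int, int]]]:
    """Pairwise intersections of positive length, with the (i, j) row-index
    pairs of the contributing intervals of `a` and `b`."""
    a_df, b_df = a.df, b.df
    rows: list[tuple] = []
    pairs: list[tuple[int, int]] = []
    a_groups = {c: g for c, g in a_df.groupby("chrom", sort=True)}
    b_groups = {c: g for c, g in b_df.groupby("chrom", sort=True)}
    for chrom in sorted(set(a_groups) & set(b_groups)):
        ga, gb = a_groups[chrom], b_groups[chrom]
        ai, bi = ga.index.to_numpy(), gb.index.to_numpy()
        a_s, a_e = ga["start"].to_numpy(), ga["end"].to_numpy()
        b_s, b_e = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        # two-pointer sweep; fall back over all active b for each a
        for i in range(len(a_s)):
            while j < len(b_s) and b_e[j] <= a_s[i]:
                j += 1
            k = j
            while k < len(b_s) and b_s[k] < a_e[i]:
                s = max(a_s[i], b_s[k])
                e = min(a_e[i], b_e[k])
                if s < e:
                    rows.append((chrom, s, e))
                    pairs.append((int(ai[i]), int(bi[k])))
                k += 1
    out = RegionSet.from_tuples(rows, a.chrom_sizes or b.chrom_sizes)
    return out, pairs


def consensus_peaks(group_peak_sets: Sequence[RegionSet]) -> RegionSet:
    """Consensus peak set: the merged union of per-group peak sets."""
    if len(group_peak_sets) == 0:
        raise ValueError("need at least one peak set")
    df = pd.concat([rs.df[["chrom", "start", "end"]] for rs in group_peak_sets],
                   ignore_index=True)
    sizes = next((rs.chrom_sizes for rs in group_peak_sets if rs.chrom_sizes), None)
    return merge_regions(RegionSet(df, sizes))


def subtract_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Bases of `a` not covered by `b` (both merged internally)."""
    a = merge_regions(a)
    bm = merge_regions(b).by_chrom()
    rows = []
    for chrom, (starts, ends) in a.by_chrom().items():
        if chrom not in bm:
            rows.extend((chrom, s, e) for s, e in zip(starts, ends))
            continue
        b_s, b_e = bm[chrom]
        for s, e in zip(starts, ends):
            cur = s
            idx = np.searchsorted(b_e, s, side="right")
            while idx < len(b_s) and b_s[idx] < e:
                if b_s[idx] > cur:
                    rows.append((chrom, cur, min(b_s[idx], e)))
                cur = max(cur, b_e[idx])
                idx += 1
            if cur < e:
                rows.append((chrom, cur, e))
    return RegionSet.from_tuples(rows, a.chrom_sizes)


# ---------------------------------------------------------------------------
# Annotation geometry
# ---------------------------------------------------------------------------

def tss_positions(genes: RegionSet) -> pd.DataFrame:
    """TSS per gene: start for + strand, end for - strand."""
    df = genes.df
    if "strand" not in df.columns or df["strand"].isin([".", None]).any():
        raise ValueError("genes must carry '+'/'-' strand to define TSSs")
    tss = np.where(df["strand"] == "+", df["start"], df["end"])
    return pd.DataFrame({"chrom": df["chrom"], "tss": tss,
                         "name": df.get("name", pd.Series(range(len(df)))).astype(str),
                         "strand": df["strand"]})


def define_promoters(genes: RegionSet, up: int = 1000, down: int = 100) -> RegionSet:
    """Promoters: ``up`` bp upstream to ``down`` bp downstream of each TSS.

    For a + strand gene with TSS t the promoter is [t-up, t+down); for a
    - strand gene (TSS = interval end) it is [t-down, t+up).  Intervals are
    clipped to chromosome bounds when sizes are known (and to zero always).
    """
    t = tss_positions(genes)
    plus = t["strand"] == "+"
    start = np.where(plus, t["tss"] - up, t["tss"] - down)
    end = np.where(plus, t["tss"] + down, t["tss"] + up)
    start = np.maximum(start, 0)
    if genes.chrom_sizes is not None:
        lim = t["chrom"].map(genes.chrom_sizes).to_numpy()
        end = np.minimum(end, lim)
    df = pd.DataFrame({"chrom": t["chrom"], "start": start, "end": end,
                       "name": t["name"], "strand": t["strand"]})
    df = df[df["start"] < df["end"]]
    return RegionSet(df, genes.chrom_sizes)


def define_distal_promoters(genes: RegionSet, near: int = 1000, far: int = 3000) -> RegionSet:
    """Distal promoters: ``near``-``far`` bp upstream of each TSS."""
    t = tss_positions(genes)
    plus = t["strand"] == "+"
    start = np.where(plus, t["tss"] - far, t["tss"] + near)
    end = np.where(plus, t["tss"] - near, t["tss"] + far)
    start = np.maximum(start, 0)
    if genes.chrom_sizes is not None:
        lim = t["chrom"].map(genes.chrom_sizes).to_numpy()
        end = np.minimum(end, lim)
    df = pd.DataFrame({"chrom": t["chrom"], "start": start, "end": end, "name": t["name"]})
    df = df[df["start"] < df["end"]]
    return RegionSet(df, genes.chrom_sizes)


def cpg_shores_shelves(islands: RegionSet) -> tuple[RegionSet, RegionSet]:
    """CpG shores (0-2000 bp flanks) and shelves (2000-4000 bp flanks).

    Shores are the 2 kb flanks minus the (merged) islands; shelves are the
    next 2 kb minus islands and shores, so the three classes never overlap.
    """
    islands = merge_regions(islands)
    sizes = islands.chrom_sizes

    def _flanks(width_inner: int, width_outer: int) -> RegionSet:
        rows = []
        for chrom, s, e in islands.df[["chrom", "start", "end"]].itertuples(index=False):
            lim = sizes.get(chrom) if sizes else None
            ls, le = max(0, s - width_outer), max(0, s - width_inner)
            rs, re = e + width_inner, e + width_outer
            if lim is not None:
                rs, re = min(rs, lim), min(re, lim)
            if ls < le:
                rows.append((chrom, ls, le))
            if rs < re:
                rows.append((chrom, rs, re))
        return RegionSet.from_tuples(rows, sizes) if rows else RegionSet.from_tuples([], sizes)

    near = merge_regions(_flanks(0, 2000)) if len(islands) else islands
    outer = merge_regions(_flanks(0, 4000)) if len(islands) else islands
    shores = subtract_regions(near, islands)
    shelves = subtract_regions(subtract_regions(outer, islands), near)
    return shores, shelves


def build_background(chrom_sizes: Mapping[str, int], blacklist: RegionSet | None = None,
                     bin: int = 200) -> RegionSet:
    """Genome minus blacklist, chopped into <=``bin``-sized tiles.

    Total tiled bases equal genome length minus blacklisted bases.
    """
    genome = RegionSet.from_tuples(
        [(c, 0, l) for c, l in sorted(chrom_sizes.items())], chrom_sizes)
    if blacklist is not None and len(blacklist):
        genome = subtract_regions(genome, blacklist)
    rows = []
    for chrom, s, e in genome.df[["chrom", "start", "end"]].itertuples(index=False):
        edges = np.arange(s, e, bin)
        for bs in edges:
            rows.append((chrom, bs, min(bs + bin, e)))
    return RegionSet.from_tuples(rows, chrom_sizes)


@dataclass
class AnnotationLabel:
    region_id: str
    gene_context: str   # promoter | distal_promoter | gene_body | intergenic
    cpg_context: str    # island | shore | shelf | open_sea
    nearest_gene: str


def _overlaps_any(regions: RegionSet, other: RegionSet) -> np.ndarray:
    """Boolean per region of `regions`: overlaps >=1 interval of `other`."""
    out = np.zeros(len(regions), dtype=bool)
    om = merge_regions(other).by_chrom() if len(other) else {}
    for chrom, sub in regions.df.groupby("chrom", sort=False):
        if chrom not in om:
            continue
        b_s, b_e = om[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        # region [s,e) overlaps some [bs,be) iff exists bs < e and be > s
        idx = np.searchsorted(b_e, s, side="right")
        hit = (idx < len(b_s)) & (b_s[np.minimum(idx, len(b_s) - 1)] < e)
        out[sub.index.to_numpy()] = hit
    return out


def annotate_regions(regions: RegionSet, genes: RegionSet, islands: RegionSet,
                     promoter_up: int = 1000, promoter_down: int = 100) -> pd.DataFrame:
    """Annotate regions with one gene-context and one CpG-context label.

    Gene context precedence: promoter > distal_promoter > gene_body >
    intergenic (overlap by >=1 bp).  CpG context precedence: island > shore >
    shelf > open_sea.  nearest_gene is the gene whose TSS is closest to the
    region (distance 0 if the TSS falls inside it); ties break to the
    lexicographically smaller gene id.
    """
    promoters = define_promoters(genes, promoter_up, promoter_down)
    distal = define_distal_promoters(genes)
    shores, shelves = cpg_shores_shelves(islands)

    n = len(regions)
    gene_ctx = np.full(n, "intergenic", dtype=object)
    for label, track in (("gene_body", genes), ("distal_promoter", distal),
                         ("promoter", promoters)):
        hit = _overlaps_any(regions, track)
        gene_ctx[hit] = label

    cpg_ctx = np.full(n, "open_sea", dtype=object)
    for label, track in (("shelf", shelves), ("shore", shores), ("island", islands)):
        if len(track):
            cpg_ctx[_overlaps_any(regions, track)] = label

    # nearest gene by TSS distance
    t = tss_positions(genes)
    nearest = np.full(n, "", dtype=object)
    for chrom, sub in regions.df.groupby("chrom", sort=False):
        tc = t[t["chrom"] == chrom]
        if tc.empty:
            continue
        tss = tc["tss"].to_numpy()
        names = tc["name"].to_numpy()
        for ridx, s, e in zip(sub.index.to_numpy(), sub["start"].to_numpy(),
                              sub["end"].to_numpy()):
            d = np.where(tss < s, s - tss, np.where(tss >= e, tss - (e - 1), 0))
            dmin = d.min()
            cands = sorted(names[d == dmin])
            nearest[ridx] = cands[0]

    ids = (regions.df["name"].astype(str).to_numpy()
           if "name" in regions.df.columns and regions.df["name"].notna().all()
           else np.array([f"r{i}" for i in range(n)], dtype=object))
    return pd.DataFrame({"region_id": ids, "gene_context": gene_ctx,
                         "cpg_context": cpg_ctx, "nearest_gene": nearest})


# ---------------------------------------------------------------------------
# Domain definitions
# ---------------------------------------------------------------------------

def define_bivalent(k4me3_consensus: RegionSet, k27me3_consensus: RegionSet) -> RegionSet:
    """Bivalent chromatin domains: merged intersections of H3K4me3 and
    H3K27me3 consensus peaks."""
    inter, _ = intersect_regions(k4me3_consensus, k27me3_consensus)
    return merge_regions(inter)


@dataclass
class SwitchDomain:
    """A heterochromatin-switch domain: a block where aging gains of
    facultative heterochromatin (H3K27me3 up) fall inside aging losses of
    constitutive heterochromatin (H3K9me3 down)."""
    chrom: str
    start: int
    end: int
    k27_der_ids: list[str] = field(default_factory=list)
    k9_der_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def _directional(regions: RegionSet, want: str) -> RegionSet:
    """Filter a labelled DER set by direction carried as '<id>|up'/'<id>|down'
    in the name field, or in a 'direction' column."""
    df = regions.df
    if len(df) == 0:
        return regions
    if "direction" in df.columns:
        if df["direction"].isna().any():
            raise ValueError("direction labels missing on some regions")
        keep = df[df["direction"] == want]
    elif "name" in df.columns and df["name"].notna().all() and \
            df["name"].astype(str).str.contains(r"\|").all():
        split = df["name"].astype(str).str.rsplit("|", n=1, expand=True)
        keep = df[split[1] == want].copy()
        keep["name"] = split.loc[keep.index, 0]
    else:
        raise ValueError(
            "DER direction labels missing: provide a 'direction' column or "
            "names of the form '<id>|up' / '<id>|down'")
    return RegionSet(keep, regions.chrom_sizes)


def detect_switch_domains(k27_ders: RegionSet, k9_ders: RegionSet
                          ) -> tuple[list[SwitchDomain], dict]:
    """Detect heterochromatin-switch domains.

    Takes direction-labelled DER sets, keeps H3K27me3 up-DERs and H3K9me3
    down-DERs, intersects them and merges contiguous intersection blocks into
    domains, recording the contributing DER ids for each.  Returns the domain
    list and a summary with the domain count and mean length in bp.
    """
    k27_up = _directional(k27_ders, "up")
    k9_down = _directional(k9_ders, "down")
    inter, pairs = intersect_regions(k27_up, k9_down)
    merged = merge_regions(inter)
    domains: list[SwitchDomain] = []
    for chrom, s, e in merged.df[["chrom", "start", "end"]].itertuples(index=False):
        dom = SwitchDomain(chrom, int(s), int(e))
        domains.append(dom)
    # map contributing DER ids onto merged domains
    if pairs:
        k27_names = (k27_up.df["name"].astype(str).to_numpy()
                     if "name" in k27_up.df.columns else
                     np.array([f"k27_{i}" for i in range(len(k27_up))], dtype=object))
        k9_names = (k9_down.df["name"].astype(str).to_numpy()
                    if "name" in k9_down.df.columns else
                    np.array([f"k9_{i}" for i in range(len(k9_down))], dtype=object))
        for (i, j), (chrom, s, e) in zip(pairs,
                                         inter.df[["chrom", "start", "end"]]
                                         .itertuples(index=False, name=None)):
            for dom in domains:
                if dom.chrom == chrom and s < dom.end and e > dom.start:
                    if k27_names[i] not in dom.k27_der_ids:
                        dom.k27_der_ids.append(k27_names[i])
                    if k9_names[j] not in dom.k9_der_ids:
                        dom.k9_der_ids.append(k9_names[j])
                    break
    summary = {
        "count": len(domains),
        "mean_length_bp": float(np.mean([d.length for d in domains])) if domains else 0.0,
    }
    return domains, summary


def switch_methylation_trend(domain_meth_old: Sequence[float],
                             domain_meth_young: Sequence[float]
                             ) -> tuple[float, int]:
    """Fraction of switch domains whose mean methylation increases with age.

    Inputs are aligned per-domain mean beta values for old and young samples;
    NaN entries (domains with no covered CpGs) are excluded and their count
    reported.  Ties count as not increased.
    """
    old = np.asarray(domain_meth_old, dtype=float)
    young = np.asarray(domain_meth_young, dtype=float)
    if old.shape != young.shape:
        raise ValueError("old/young per-domain vectors must align")
    ok = ~(np.isnan(old) | np.isnan(young))
    n_excluded = int((~ok).sum())
    if ok.sum() == 0:
        return float("nan"), n_excluded
    frac = float(np.mean((old[ok] - young[ok]) > 0))
    return frac, n_excluded


# ---------------------------------------------------------------------------
# BED I/O (tab-separated, no header)
# ---------------------------------------------------------------------------

def read_bed(path, chrom_sizes: Mapping[str, int] | None = None) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED_COLS[: df.shape[1]]
    df = df.dropna(axis=1, how="all")
    return RegionSet(df, chrom_sizes)


def write_bed(regions: RegionSet, path) -> None:
    df = regions.df.copy()
    cols = [c for c in _BED_COLS if c in df.columns]
    # BED is positional: score requires name, strand requires score
    if "strand" in cols and "score" not in cols:
        df["score"] = 0
    if ("score" in df.columns or "strand" in cols) and "name" not in cols:
        df["name"] = "."
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
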