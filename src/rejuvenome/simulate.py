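"""Synthetic multi-omic dataset generator with planted ground truth.

The generator emulates the statistical structure of a 4-group (young/old x
control/enriched, "YC/YE/OC/OE") bulk multi-omic study of a tissue:

* RNA, ATAC and six histone-mark ChIP count matrices drawn from a negative
  binomial with feature-wise dispersion and log-normal library size factors;
* bidirectional aging effects, a fraction of which are partially reversed by
  environmental enrichment (EE) in both age groups, and an independent
  fraction "rejuvenated" (shifted in old-control samples only);
* planted bivalent domains (co-located H3K4me3/H3K27me3 peaks with paired
  aging loss) and heterochromatin-switch blocks (broad H3K9me3 aging-loss
  blocks containing H3K27me3 aging-gain peaks) with a planted methylation
  up-trend in a configurable fraction of switch domains;
* a protein layer derived from high-expression genes with independent noise
  and protein-specific effects, plus a log-normal half-life table;
* per-CpG methylation counts at the pooled-CpG level (binomial methylated
  counts over Poisson coverage).

Every random stream is split per layer from the master seed so adding a
layer does not perturb the others; identical configs produce byte-identical
datasets on disk.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionSet, write_bed, read_bed

MARKS = ["H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K27me3", "H3K9me3"]
GROUPS = ["YC", "YE", "OC", "OE"]

TRUTH_SCHEMA_VERSION = "1.0"


class SizingError(ValueError):
    """Requested features do not fit in the configured genome."""


@dataclass
class SimConfig:
    """Full specification of a synthetic dataset.

    Proportions are in [0, 1]; ``frac_reversed`` and ``frac_old_rejuvenated``
    are fractions of the aging-affected features and must sum to <= 1.
    """

    n_chrom: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 2000
    n_peaks_per_mark: int = 1500
    n_cpgs: int = 50_000
    n_reps_per_group: int = 3
    nb_dispersion: float = 0.05
    base_mean_log2_range: tuple[float, float] = (3.0, 12.0)
    frac_aging_de: float = 0.15
    aging_lfc: float = 1.5
    frac_reversed: float = 0.6
    frac_old_rejuvenated: float = 0.2
    frac_ee_independent: float = 0.05
    ee_scale_young: float = 0.8
    ee_scale_old: float = 0.8
    n_switch_domains: int = 10
    switch_block_length: int = 40_000
    n_bivalent_domains: int = 20
    methyl_depth: float = 30.0
    global_meth: float = 0.76
    switch_meth_frac: float = 0.78
    switch_meth_shift: float = 0.05
    n_proteins: int = 600
    protein_noise_sd: float = 0.25
    protein_offset_sd: float = 2.0
    protein_tech_sd: float = 0.1
    n_techreps: int = 2
    frac_protein_specific: float = 0.1
    sf_sigma: float = 0.15
    n_islands: int = 800
    blacklist_per_chrom: int = 2
    blacklist_length: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_aging_de", "frac_reversed", "frac_old_rejuvenated",
                     "frac_ee_independent", "switch_meth_frac", "global_meth",
                     "frac_protein_specific"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_reversed + self.frac_old_rejuvenated > 1.0:
            raise ValueError("frac_reversed + frac_old_rejuvenated must be <= 1")
        for name in ("n_chrom", "chrom_length", "n_genes", "n_peaks_per_mark",
                     "n_cpgs", "n_reps_per_group", "n_switch_domains",
                     "n_bivalent_domains", "switch_block_length", "n_proteins",
                     "n_techreps", "n_islands"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        for name in ("n_chrom", "chrom_length", "n_genes", "n_reps_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.base_mean_log2_range
        if not lo < hi:
            raise ValueError("base_mean_log2_range must be (lo, hi) with lo < hi")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_mean_log2_range"] = list(d["base_mean_log2_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "base_mean_log2_range" in d:
            d["base_mean_log2_range"] = tuple(d["base_mean_log2_range"])
        return cls(**d)


@dataclass
class GenomeLayout:
    chrom_sizes: dict[str, int]
    genes: RegionSet
    islands: RegionSet
    blacklist: RegionSet


@dataclass
class CountMatrix:
    counts: pd.DataFrame          # features x samples, int
    samples: pd.DataFrame         # sample sheet
    regions: RegionSet | None = None


@dataclass
class MultiOmicDataset:
    config: SimConfig
    layout: GenomeLayout
    samples: pd.DataFrame
    rna: CountMatrix
    atac: CountMatrix
    chip: dict[str, CountMatrix]
    protein: pd.DataFrame              # log2, proteins x (bio sample x techrep)
    protein_samples: pd.DataFrame
    halflife: pd.Series
    methylation: pd.DataFrame          # chrom, pos, meth, total, sample
    truth: pd.DataFrame                # TruthTable
    switch_domains: RegionSet          # planted switch blocks w/ meth trend in name
    bivalent_domains: RegionSet


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

class _Occupancy:
    """Per-chromosome sorted non-overlap bookkeeping for interval placement."""

    def __init__(self, chrom_sizes: dict[str, int]):
        self.sizes = chrom_sizes
        self.iv: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.iv[chrom]
        i = bisect_left(ivs, (start, start))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self.iv[chrom], (start, end))


def _place(rng: np.random.Generator, lengths: list[int], chrom_sizes: dict[str, int],
           occ: _Occupancy, extra: list[_Occupancy] | None = None,
           what: str = "feature", max_tries: int = 200) -> list[tuple[str, int, int]]:
    """Place non-overlapping intervals by rejection sampling.

    Raises :class:`SizingError` when an interval cannot be placed, naming the
    constraint that failed.
    """
    chroms = sorted(chrom_sizes)
    clens = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed = []
    for k, L in enumerate(lengths):
        ok = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=clens / clens.sum()))
            chrom = chroms[ci]
            if chrom_sizes[chrom] < L:
                continue
            s = int(rng.integers(0, chrom_sizes[chrom] - L + 1))
            e = s + L
            if occ.conflicts(chrom, s, e):
                continue
            if extra and any(o.conflicts(chrom, s, e) for o in extra):
                continue
            occ.add(chrom, s, e)
            placed.append((chrom, s, e))
            ok = True
            break
        if not ok:
            raise SizingError(
                f"could not place {what} {k + 1}/{len(lengths)} of length {L} bp: "
                f"genome too crowded for the requested feature counts")
    return placed


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig) -> GenomeLayout:
    """Generate chromosome sizes, non-overlapping stranded genes, CpG islands
    preferentially near TSSs, and a small blacklist. Deterministic per seed."""
    config.validate()
    rng = _layer_rng(config.seed, "genome")
    chrom_sizes = {f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chrom)}

    occ_black = _Occupancy(chrom_sizes)
    bl = _place(rng, [config.blacklist_length] * (config.blacklist_per_chrom * config.n_chrom),
                chrom_sizes, occ_black, what="blacklist region")
    blacklist = RegionSet.from_tuples(
        [(c, s, e, f"bl{i:03d}") for i, (c, s, e) in enumerate(sorted(bl))], chrom_sizes)

    occ_genes = _Occupancy(chrom_sizes)
    glens = rng.integers(2000, 10001, size=config.n_genes).tolist()
    gpos = _place(rng, glens, chrom_sizes, occ_genes, extra=[occ_black], what="gene")
    strands = rng.choice(["+", "-"], size=config.n_genes)
    order = np.lexsort(([s for _, s, _ in gpos], [c for c, _, _ in gpos]))
    genes = RegionSet.from_tuples(
        [(gpos[i][0], gpos[i][1], gpos[i][2], f"g{k:05d}", 0.0, strands[i])
         for k, i in enumerate(order)], chrom_sizes)

    # CpG islands: ~60% anchored at TSSs, rest random; non-overlapping
    occ_isl = _Occupancy(chrom_sizes)
    n_tss = min(int(0.6 * config.n_islands), config.n_genes)
    tss_rows = genes.df.sample(n=n_tss, random_state=int(rng.integers(2**31)))
    rows = []
    for _, g in tss_rows.iterrows():
        L = int(rng.integers(500, 1501))
        t = g["start"] if g["strand"] == "+" else g["end"]
        s = max(0, int(t - L // 2))
        e = min(chrom_sizes[g["chrom"]], s + L)
        if s < e and not occ_isl.conflicts(g["chrom"], s, e) \
                and not occ_black.conflicts(g["chrom"], s, e):
            occ_isl.add(g["chrom"], s, e)
            rows.append((g["chrom"], s, e))
    n_rand = config.n_islands - len(rows)
    if n_rand > 0:
        rlens = rng.integers(500, 1501, size=n_rand).tolist()
        rows += _place(rng, rlens, chrom_sizes, occ_isl, extra=[occ_black], what="CpG island")
    rows = sorted(rows)
    islands = RegionSet.from_tuples(
        [(c, s, e, f"cgi{i:04d}") for i, (c, s, e) in enumerate(rows)], chrom_sizes)
    return GenomeLayout(chrom_sizes, genes, islands, blacklist)


def _layer_rng(seed: int, layer: str) -> np.random.Generator:
    # crc32 is stable across processes (unlike hash(), which is salted)
    ss = np.random.SeedSequence([int(seed), zlib.crc32(layer.encode()) % (2**31)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Effect assignment and count sampling
# ---------------------------------------------------------------------------

def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for grp in GROUPS:
        age = "young" if grp[0] == "Y" else "old"
        env = "ctrl" if grp[1] == "C" else "ee"
        for r in range(1, config.n_reps_per_group + 1):
            sid = f"{grp}{r}"
            rows.append((sid, age, env, r, sid))
    return pd.DataFrame(rows, columns=["sample", "age", "env", "replicate",
                                       "techrep_group"])


def _assign_classes(rng: np.random.Generator, n: int, config: SimConfig,
                    forced: dict[int, tuple[str, str, float]] | None = None
                    ) -> pd.DataFrame:
    """Per-feature aging/EE class and planted lfc.

    ``forced`` maps feature index -> (aging_class, ee_class, lfc) for
    domain-planted features whose direction is fixed by construction.
    """
    aging = np.full(n, "null", dtype=object)
    ee = np.full(n, "null", dtype=object)
    lfc = np.zeros(n)
    forced = forced or {}
    free = np.array([i for i in range(n) if i not in forced])
    n_de = round(config.frac_aging_de * n)
    n_de = min(n_de, len(free))
    de_idx = rng.choice(free, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    rng.shuffle(signs)
    n_rev = round(config.frac_reversed * n_de)
    n_rej = round(config.frac_old_rejuvenated * n_de)
    for k, i in enumerate(de_idx):
        aging[i] = "up" if signs[k] > 0 else "down"
        lfc[i] = signs[k] * config.aging_lfc
        if k < n_rev:
            ee[i] = "reversed"
        elif k < n_rev + n_rej:
            ee[i] = "old_rejuvenated"
    # EE-independent features among the remaining nulls
    rest = np.array([i for i in free if aging[i] == "null"])
    n_ind = min(round(config.frac_ee_independent * n), len(rest))
    ind_idx = rng.choice(rest, size=n_ind, replace=False) if n_ind else np.array([], dtype=int)
    for k, i in enumerate(ind_idx):
        ee[i] = "independent"
        lfc[i] = (1.0 if k % 2 == 0 else -1.0) * config.ee_scale_young * config.aging_lfc
    for i, (a, e, v) in forced.items():
        aging[i], ee[i], lfc[i] = a, e, v
    return pd.DataFrame({"aging_class": aging, "ee_class": ee, "planted_lfc": lfc})


def group_log2_means(base: np.ndarray, classes: pd.DataFrame, config: SimConfig
                     ) -> dict[str, np.ndarray]:
    """Planted per-group log2 means encoding the aging/EE effect structure.

    * aging only: old groups shifted by the planted lfc;
    * reversed: EE shifts opposite to aging in both ages (scaled);
    * old_rejuvenated: only OC is shifted (YC ~ YE ~ OE);
    * independent: EE shift in both ages, no aging effect.
    """
    b = base.astype(float)
    lfc = classes["planted_lfc"].to_numpy()
    ee = classes["ee_class"].to_numpy()
    aging = classes["aging_class"].to_numpy()
    has_aging = aging != "null"
    m = {g: b.copy() for g in GROUPS}
    is_rej = ee == "old_rejuvenated"
    is_rev = ee == "reversed"
    is_ind = ee == "independent"
    aging_plain = has_aging & ~is_rej
    m["OC"][aging_plain] += lfc[aging_plain]
    m["OE"][aging_plain] += lfc[aging_plain]
    m["OC"][is_rej] += lfc[is_rej]
    m["YE"][is_rev] -= config.ee_scale_young * lfc[is_rev]
    m["OE"][is_rev] -= config.ee_scale_old * lfc[is_rev]
    m["YE"][is_ind] += lfc[is_ind]
    m["OE"][is_ind] += lfc[is_ind]
    return m


def sample_size_factors(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    sf = np.exp(rng.normal(0.0, sigma, size=n))
    return sf / np.exp(np.mean(np.log(sf)))


def sample_nb_counts(rng: np.random.Generator, group_means: dict[str, np.ndarray],
                     samples: pd.DataFrame, size_factors: np.ndarray,
                     alpha: float) -> pd.DataFrame:
    """Counts ~ NB(mean_i * sf_s * 2^effects, alpha); Poisson when alpha=0."""
    groups = (samples["age"].map({"young": "Y", "old": "O"})
              + samples["env"].map({"ctrl": "C", "ee": "E"}))
    cols = {}
    for j, (sid, grp) in enumerate(zip(samples["sample"], groups)):
        mu = (2.0 ** group_means[grp]) * size_factors[j]
        if alpha <= 0:
            cols[sid] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            p = r / (r + mu)
            cols[sid] = rng.negative_binomial(r, p)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Layer generators
# ---------------------------------------------------------------------------

def generate_counts(layout: GenomeLayout, config: SimConfig
                    ) -> tuple[CountMatrix, CountMatrix, dict[str, CountMatrix],
                               pd.DataFrame, RegionSet, RegionSet]:
    """RNA, ATAC and per-mark ChIP count matrices plus the TruthTable and the
    planted switch/bivalent domain sets."""
    config.validate()
    samples = make_sample_sheet(config)
    lo, hi = config.base_mean_log2_range
    truth_frames = []

    # ---- RNA ----
    rng = _layer_rng(config.seed, "rna")
    sf = sample_size_factors(rng, len(samples), config.sf_sigma)
    base = rng.uniform(lo, hi, size=config.n_genes)
    classes = _assign_classes(rng, config.n_genes, config)
    means = group_log2_means(base, classes, config)
    counts = sample_nb_counts(rng, means, samples, sf, config.nb_dispersion)
    gene_ids = layout.genes.df["name"].astype(str).to_numpy()
    counts.index = pd.Index(gene_ids, name="feature_id")
    rna = CountMatrix(counts, samples, layout.genes)
    truth_frames.append(pd.DataFrame({
        "feature_id": gene_ids, "layer": "rna", **classes.to_dict("list"),
        "domain_membership": "none"}))
    rna_base_log2 = base  # reused by the protein layer

    # ---- peak placement with planted domain structure ----
    rng_pk = _layer_rng(config.seed, "peaks")
    chrom_sizes = layout.chrom_sizes
    occ_black = _Occupancy(chrom_sizes)
    for c, s, e in layout.blacklist.df[["chrom", "start", "end"]].itertuples(index=False):
        occ_black.add(c, s, e)

    # switch + decoy (non-switch) H3K9me3 blocks
    occ_k9 = _Occupancy(chrom_sizes)
    n_blocks = 2 * config.n_switch_domains
    blocks = _place(rng_pk, [config.switch_block_length] * n_blocks, chrom_sizes,
                    occ_k9, extra=[occ_black], what="H3K9me3 block")
    switch_blocks = blocks[: config.n_switch_domains]
    decoy_blocks = blocks[config.n_switch_domains:]

    # bivalent domain anchors (shared K4me3/K27me3 intervals)
    occ_biv = _Occupancy(chrom_sizes)
    biv = _place(rng_pk, rng_pk.integers(1000, 3001, size=config.n_bivalent_domains).tolist(),
                 chrom_sizes, occ_biv, extra=[occ_black, occ_k9], what="bivalent domain")

    peak_sets: dict[str, list[tuple[str, int, int]]] = {}
    forced_by_mark: dict[str, dict[int, tuple[str, str, float]]] = {m: {} for m in MARKS}
    switch_k27: list[tuple[str, int, int]] = []
    occ_k27all = _Occupancy(chrom_sizes)  # K9/K27 co-occurrence only in switch blocks
    for mark in MARKS:
        occ = _Occupancy(chrom_sizes)
        peaks: list[tuple[str, int, int]] = []
        forced = forced_by_mark[mark]
        if mark == "H3K9me3":
            for c, s, e in switch_blocks:
                forced[len(peaks)] = ("down", "null", -config.aging_lfc)
                peaks.append((c, s, e))
                occ.add(c, s, e)
            for c, s, e in decoy_blocks:
                forced[len(peaks)] = ("down", "null", -config.aging_lfc)
                peaks.append((c, s, e))
                occ.add(c, s, e)
            n_rest = max(0, config.n_peaks_per_mark - len(peaks))
            lens = rng_pk.integers(3000, 10001, size=n_rest).tolist()
            peaks += _place(rng_pk, lens, chrom_sizes, occ,
                            extra=[occ_black, occ_biv, occ_k27all],
                            what=f"{mark} peak")
        elif mark == "H3K27me3":
            # aging-gain peaks planted inside each switch block
            for c, s, e in switch_blocks:
                k = int(rng_pk.integers(2, 5))
                width = (e - s) // (2 * k)
                for q in range(k):
                    ps = s + q * (e - s) // k + int(rng_pk.integers(0, max(1, width)))
                    pe = min(e, ps + int(rng_pk.integers(1000, 3001)))
                    if ps < pe:
                        forced[len(peaks)] = ("up", "null", config.aging_lfc)
                        peaks.append((c, ps, pe))
                        occ.add(c, ps, pe)
            for c, s, e in biv:
                forced[len(peaks)] = ("down", "null", -config.aging_lfc)
                peaks.append((c, s, e))
                occ.add(c, s, e)
            switch_k27 = [p for i, p in enumerate(peaks) if forced.get(i, ("",))[0] == "up"]
            n_rest = max(0, config.n_peaks_per_mark - len(peaks))
            lens = rng_pk.integers(1000, 3001, size=n_rest).tolist()
            # ordinary K27 peaks avoid all K9 blocks so no spurious switch
            peaks += _place(rng_pk, lens, chrom_sizes, occ,
                            extra=[occ_black, occ_k9], what=f"{mark} peak")
            for c, s, e in peaks:
                occ_k27all.add(c, s, e)
        elif mark == "H3K4me3":
            for c, s, e in biv:
                forced[len(peaks)] = ("down", "null", -config.aging_lfc)
                peaks.append((c, s, e))
                occ.add(c, s, e)
            n_rest = max(0, config.n_peaks_per_mark - len(peaks))
            lens = rng_pk.integers(500, 2001, size=n_rest).tolist()
            peaks += _place(rng_pk, lens, chrom_sizes, occ,
                            extra=[occ_black, occ_biv], what=f"{mark} peak")
        else:
            lens = rng_pk.integers(500, 2001, size=config.n_peaks_per_mark).tolist()
            peaks = _place(rng_pk, lens, chrom_sizes, occ, extra=[occ_black],
                           what=f"{mark} peak")
        peak_sets[mark] = peaks

    # ---- ChIP counts per mark ----
    chip: dict[str, CountMatrix] = {}
    for mark in MARKS:
        rng_m = _layer_rng(config.seed, f"chip:{mark}")
        peaks = peak_sets[mark]
        n = len(peaks)
        sf_m = sample_size_factors(rng_m, len(samples), config.sf_sigma)
        base_m = rng_m.uniform(lo, hi, size=n)
        classes_m = _assign_classes(rng_m, n, config, forced=forced_by_mark[mark])
        means_m = group_log2_means(base_m, classes_m, config)
        counts_m = sample_nb_counts(rng_m, means_m, samples, sf_m, config.nb_dispersion)
        ids = np.array([f"{mark}_p{i:05d}" for i in range(n)], dtype=object)
        counts_m.index = pd.Index(ids, name="feature_id")
        membership = np.full(n, "none", dtype=object)
        for i, (a, _, _) in forced_by_mark[mark].items():
            if mark == "H3K9me3" and i < config.n_switch_domains:
                membership[i] = "switch"
            elif mark == "H3K27me3" and a == "up":
                membership[i] = "switch"
            elif a == "down" and mark in ("H3K4me3", "H3K27me3"):
                membership[i] = "bivalent"
        regions = RegionSet.from_tuples(
            [(c, s, e, ids[i]) for i, (c, s, e) in enumerate(peaks)],
            chrom_sizes)
        chip[mark] = CountMatrix(counts_m, samples, regions)
        truth_frames.append(pd.DataFrame({
            "feature_id": ids, "layer": mark, **classes_m.to_dict("list"),
            "domain_membership": membership}))

    # ---- ATAC ----
    rng_a = _layer_rng(config.seed, "atac")
    occ_a = _Occupancy(chrom_sizes)
    lens = rng_a.integers(300, 1501, size=config.n_peaks_per_mark).tolist()
    apos = _place(rng_a, lens, chrom_sizes, occ_a, extra=[occ_black], what="ATAC peak")
    sf_a = sample_size_factors(rng_a, len(samples), config.sf_sigma)
    base_a = rng_a.uniform(lo, hi, size=len(apos))
    classes_a = _assign_classes(rng_a, len(apos), config)
    means_a = group_log2_means(base_a, classes_a, config)
    counts_a = sample_nb_counts(rng_a, means_a, samples, sf_a, config.nb_dispersion)
    aids = np.array([f"atac_p{i:05d}" for i in range(len(apos))], dtype=object)
    counts_a.index = pd.Index(aids, name="feature_id")
    atac = CountMatrix(counts_a, samples,
                       RegionSet.from_tuples(
                           [(c, s, e, aids[i]) for i, (c, s, e) in enumerate(apos)],
                           chrom_sizes))
    truth_frames.append(pd.DataFrame({
        "feature_id": aids, "layer": "atac", **classes_a.to_dict("list"),
        "domain_membership": "none"}))

    switch_rs = RegionSet.from_tuples(
        [(c, s, e, f"switch{i:03d}") for i, (c, s, e) in enumerate(sorted(switch_blocks))],
        chrom_sizes)
    bivalent_rs = RegionSet.from_tuples(
        [(c, s, e, f"biv{i:03d}") for i, (c, s, e) in enumerate(sorted(biv))],
        chrom_sizes)
    truth = pd.concat(truth_frames, ignore_index=True)
    # stash the RNA base means for the protein layer
    truth.attrs["rna_base_log2"] = rna_base_log2
    return rna, atac, chip, truth, switch_rs, bivalent_rs


def generate_methylation(layout: GenomeLayout, config: SimConfig,
                         switch_domains: RegionSet, samples: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample pooled CpG methylation counts.

    Per-CpG baseline beta is drawn around the configured global mean
    (Beta-distributed).  CpGs inside switch domains receive an old-young
    shift: positive for a ``switch_meth_frac`` fraction of domains, negative
    (same magnitude) for the rest, so the planted up-trend fraction is the
    expectation recovered by ``switch_methylation_trend``.  Coverage is
    Poisson(methyl_depth); methylated counts are Binomial(coverage, beta).

    Returns the long-format count table and a per-domain trend Series
    (+1 up-shifted / -1 down-shifted) indexed by domain name.
    """
    rng = _layer_rng(config.seed, "methylation")
    chroms = sorted(layout.chrom_sizes)

    # guarantee CpGs inside every switch domain, rest uniform
    pos_rows = []
    for c, s, e in switch_domains.df[["chrom", "start", "end"]].itertuples(index=False):
        # dense CpG coverage inside switch domains (~4/kb) so the per-domain
        # trend is measurable even over short DER intersections
        n_in = min(max(1, 4 * (e - s) // 1000), e - s)
        p = np.sort(rng.choice(np.arange(s, e), size=n_in, replace=False))
        pos_rows.append(pd.DataFrame({"chrom": c, "pos": p}))
    n_rest = config.n_cpgs - sum(len(p) for p in pos_rows)
    clens = np.array([layout.chrom_sizes[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=max(0, n_rest), p=clens / clens.sum())
    rest = pd.DataFrame({"chrom": [chroms[i] for i in ci],
                         "pos": rng.integers(0, clens[ci]).astype(np.int64)})
    cpgs = pd.concat(pos_rows + [rest], ignore_index=True)
    cpgs = cpgs.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    cpgs = cpgs.reset_index(drop=True)

    k = 20.0  # beta concentration around the global mean
    beta0 = rng.beta(config.global_meth * k, (1 - config.global_meth) * k,
                     size=len(cpgs))

    # domain shift assignment: exact count of up-shifted domains
    n_dom = len(switch_domains)
    n_up = round(config.switch_meth_frac * n_dom)
    trend = np.full(n_dom, -1, dtype=int)
    up_idx = rng.choice(n_dom, size=n_up, replace=False) if n_dom else np.array([], int)
    trend[up_idx] = 1
    dom_names = (switch_domains.df["name"].astype(str).to_numpy()
                 if n_dom else np.array([], dtype=object))
    dom_trend = pd.Series(trend, index=dom_names, name="meth_trend")

    # per-CpG old-age shift
    shift = np.zeros(len(cpgs))
    dom_by_chrom = switch_domains.by_chrom()
    names_by_chrom = {c: g["name"].astype(str).to_numpy()
                      for c, g in switch_domains.df.groupby("chrom")}
    for chrom, sub in cpgs.groupby("chrom"):
        if chrom not in dom_by_chrom:
            continue
        d_s, d_e = dom_by_chrom[chrom]
        names = names_by_chrom[chrom]
        p = sub["pos"].to_numpy()
        j = np.searchsorted(d_s, p, side="right") - 1
        inside = (j >= 0) & (p < d_e[np.maximum(j, 0)])
        tr = dom_trend.loc[names[np.maximum(j, 0)]].to_numpy()
        shift[sub.index.to_numpy()[inside]] = (tr[inside] * config.switch_meth_shift)

    rows = []
    old = (samples["age"] == "old").to_numpy()
    for j, sid in enumerate(samples["sample"]):
        beta = np.clip(beta0 + (shift if old[j] else 0.0), 0.0, 1.0)
        total = rng.poisson(config.methyl_depth, size=len(cpgs))
        meth = rng.binomial(total, beta)
        rows.append(pd.DataFrame({"chrom": cpgs["chrom"], "pos": cpgs["pos"],
                                  "meth": meth, "total": total, "sample": sid}))
    table = pd.concat(rows, ignore_index=True)
    return table, dom_trend


def generate_protein(truth: pd.DataFrame, rna: CountMatrix, config: SimConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Protein log2 abundance for a high-expression subset of genes.

    Abundance is the planted RNA group mean plus a protein-specific offset
    and Gaussian noise; a configurable fraction of proteins carry additional
    protein-specific aging/EE effects absent from the RNA truth.  Half-lives
    are log-normal.  Technical replicates add independent noise.

    Returns (log2 matrix, protein sample sheet, half-life table,
    protein truth rows).
    """
    rng = _layer_rng(config.seed, "protein")
    rna_truth = truth[truth["layer"] == "rna"].reset_index(drop=True)
    base = np.asarray(truth.attrs["rna_base_log2"])
    # high-expression subset: sample from the top 60% by planted base mean
    order = np.argsort(-base)
    pool = order[: max(config.n_proteins, int(0.6 * len(base)))]
    pick = np.sort(rng.choice(pool, size=config.n_proteins, replace=False))
    gene_ids = rna_truth.loc[pick, "feature_id"].to_numpy()

    classes = rna_truth.loc[pick, ["aging_class", "ee_class", "planted_lfc"]].copy()
    classes = classes.reset_index(drop=True)
    # protein-specific effects overwrite the shared ones for a small fraction
    n_spec = round(config.frac_protein_specific * config.n_proteins)
    spec_idx = rng.choice(config.n_proteins, size=n_spec, replace=False)
    spec_sign = np.where(rng.random(n_spec) < 0.5, 1.0, -1.0)
    for k, i in enumerate(spec_idx):
        classes.loc[i, "aging_class"] = "up" if spec_sign[k] > 0 else "down"
        classes.loc[i, "ee_class"] = "null"
        classes.loc[i, "planted_lfc"] = spec_sign[k] * config.aging_lfc

    samples = rna.samples
    offset = rng.normal(0.0, config.protein_offset_sd, size=config.n_proteins)
    means = group_log2_means(base[pick], classes, config)
    groups = (samples["age"].map({"young": "Y", "old": "O"})
              + samples["env"].map({"ctrl": "C", "ee": "E"}))
    cols, srows = {}, []
    for sid, grp in zip(samples["sample"], groups):
        bio = (means[grp] + offset
               + rng.normal(0.0, config.protein_noise_sd, size=config.n_proteins))
        for t in range(1, config.n_techreps + 1):
            col = f"{sid}_t{t}"
            cols[col] = bio + rng.normal(0.0, config.protein_tech_sd,
                                         size=config.n_proteins)
            row = samples[samples["sample"] == sid].iloc[0]
            srows.append((col, row["age"], row["env"], row["replicate"], sid))
    mat = pd.DataFrame(cols, index=pd.Index(gene_ids, name="feature_id"))
    psamples = pd.DataFrame(srows, columns=["sample", "age", "env", "replicate",
                                            "techrep_group"])
    halflife = pd.Series(np.exp(rng.normal(np.log(20.0), 0.8, size=config.n_proteins)),
                         index=mat.index, name="halflife_h")
    spec_mask = np.zeros(config.n_proteins, dtype=bool)
    spec_mask[spec_idx] = True
    ptruth = pd.DataFrame({
        "feature_id": gene_ids, "layer": "protein",
        "aging_class": classes["aging_class"], "ee_class": classes["ee_class"],
        "planted_lfc": classes["planted_lfc"],
        "domain_membership": np.where(spec_mask, "protein_specific", "none")})
    return mat, psamples, halflife, ptruth


def generate_dataset(config: SimConfig) -> MultiOmicDataset:
    """Generate the complete synthetic multi-omic dataset."""
    config.validate()
    layout = generate_genome(config)
    rna, atac, chip, truth, switch_rs, bivalent_rs = generate_counts(layout, config)
    meth, dom_trend = generate_methylation(layout, config, switch_rs, rna.samples)
    prot, psamples, halflife, ptruth = generate_protein(truth, rna, config)
    # record planted methylation trend as cpg-region truth rows
    dom_rows = pd.DataFrame({
        "feature_id": dom_trend.index, "layer": "cpg-region",
        "aging_class": np.where(dom_trend.to_numpy() > 0, "up", "down"),
        "ee_class": "null", "planted_lfc": np.where(
            dom_trend.to_numpy() > 0, config.switch_meth_shift,
            -config.switch_meth_shift),
        "domain_membership": "switch"})
    rna_base = truth.attrs.get("rna_base_log2")
    truth = pd.concat([truth, ptruth, dom_rows], ignore_index=True)
    truth.attrs["rna_base_log2"] = rna_base
    # annotate switch domains with their planted trend in the score field
    if len(switch_rs):
        sw = switch_rs.df.copy()
        sw["score"] = dom_trend.loc[sw["name"].astype(str)].to_numpy().astype(float)
        switch_rs = RegionSet(sw, switch_rs.chrom_sizes)
    return MultiOmicDataset(config, layout, rna.samples, rna, atac, chip, prot,
                            psamples, halflife, meth, truth, switch_rs, bivalent_rs)


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

TRUTH_SCHEMA = {
    "schema_version": str,
    "features": list,
    "feature_fields": list,
}
_FEATURE_FIELDS = ["feature_id", "layer", "aging_class", "ee_class",
                   "planted_lfc", "domain_membership"]


def truth_to_json(truth: pd.DataFrame) -> dict:
    feats = truth[_FEATURE_FIELDS].to_dict("records")
    return {"schema_version": TRUTH_SCHEMA_VERSION,
            "feature_fields": _FEATURE_FIELDS,
            "features": feats}


def validate_truth_json(obj: dict) -> None:
    """Minimal structural validation of a truth JSON object."""
    for key, typ in TRUTH_SCHEMA.items():
        if key not in obj:
            raise ValueError(f"truth JSON missing key '{key}'")
        if not isinstance(obj[key], typ):
            raise ValueError(f"truth JSON key '{key}' has wrong type")
    if obj["feature_fields"] != _FEATURE_FIELDS:
        raise ValueError("truth JSON feature_fields mismatch")
    for row in obj["features"]:
        if set(row) != set(_FEATURE_FIELDS):
            raise ValueError("truth JSON feature row fields mismatch")
        if row["aging_class"] not in ("up", "down", "null"):
            raise ValueError(f"invalid aging_class {row['aging_class']!r}")
        if row["ee_class"] not in ("reversed", "old_rejuvenated", "independent", "null"):
            raise ValueError(f"invalid ee_class {row['ee_class']!r}")


def write_dataset(ds: MultiOmicDataset, out_dir) -> None:
    """Write the dataset to plain-text files (TSV/BED/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(ds.layout.chrom_sizes).rename_axis("chrom").rename("length") \
        .to_csv(out / "chrom.sizes", sep="\t", header=False)
    write_bed(ds.layout.genes, out / "genes.bed")
    write_bed(ds.layout.islands, out / "cpg_islands.bed")
    write_bed(ds.layout.blacklist, out / "blacklist.bed")
    write_bed(ds.switch_domains, out / "switch_domains_truth.bed")
    write_bed(ds.bivalent_domains, out / "bivalent_domains_truth.bed")
    ds.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    ds.rna.counts.to_csv(out / "rna_counts.tsv", sep="\t")
    ds.atac.counts.to_csv(out / "atac_counts.tsv", sep="\t")
    write_bed(ds.atac.regions, out / "atac_peaks.bed")
    for mark, cm in ds.chip.items():
        cm.counts.to_csv(out / f"chip_{mark}_counts.tsv", sep="\t")
        write_bed(cm.regions, out / f"chip_{mark}_peaks.bed")
    ds.protein.to_csv(out / "protein_log2.tsv", sep="\t")
    ds.protein_samples.to_csv(out / "protein_samples.tsv", sep="\t", index=False)
    ds.halflife.rename_axis("feature_id").to_csv(out / "protein_halflife.tsv", sep="\t")
    ds.methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
    obj = truth_to_json(ds.truth)
    with open(out / "truth.json", "w") as fh:
        json.dump(obj, fh, indent=0, sort_keys=True)
    with open(out / "simconfig.json", "w") as fh:
        json.dump(ds.config.to_dict(), fh, indent=0, sort_keys=True)


def read_dataset(in_dir) -> MultiOmicDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round-trip)."""
    d = Path(in_dir)
    with open(d / "simconfig.json") as fh:
        config = SimConfig.from_dict(json.load(fh))
    sizes = pd.read_csv(d / "chrom.sizes", sep="\t", header=None,
                        names=["chrom", "length"])
    chrom_sizes = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
    layout = GenomeLayout(
        chrom_sizes,
        read_bed(d / "genes.bed", chrom_sizes),
        read_bed(d / "cpg_islands.bed", chrom_sizes),
        read_bed(d / "blacklist.bed", chrom_sizes))
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    rna_counts = pd.read_csv(d / "rna_counts.tsv", sep="\t", index_col=0)
    atac_counts = pd.read_csv(d / "atac_counts.tsv", sep="\t", index_col=0)
    atac_regions = read_bed(d / "atac_peaks.bed", chrom_sizes)
    chip = {}
    for mark in MARKS:
        chip[mark] = CountMatrix(
            pd.read_csv(d / f"chip_{mark}_counts.tsv", sep="\t", index_col=0),
            samples, read_bed(d / f"chip_{mark}_peaks.bed", chrom_sizes))
    prot = pd.read_csv(d / "protein_log2.tsv", sep="\t", index_col=0)
    psamples = pd.read_csv(d / "protein_samples.tsv", sep="\t")
    halflife = pd.read_csv(d / "protein_halflife.tsv", sep="\t", index_col=0)
    halflife = halflife.iloc[:, 0].rename("halflife_h")
    meth = pd.read_csv(d / "methylation.tsv", sep="\t")
    with open(d / "truth.json") as fh:
        obj = json.load(fh)
    validate_truth_json(obj)
    truth = pd.DataFrame(obj["features"])[_FEATURE_FIELDS]
    switch = read_bed(d / "switch_domains_truth.bed", chrom_sizes)
    bivalent = read_bed(d / "bivalent_domains_truth.bed", chrom_sizes)
    return MultiOmicDataset(config, layout, samples,
                            CountMatrix(rna_counts, samples, layout.genes),
                            CountMatrix(atac_counts, samples, atac_regions),
                            chip, prot, psamples, halflife, meth, truth,
                            switch, bivalent)
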