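"""End-to-end pipeline: simulate -> differential -> domains -> enrichment ->
curation -> recovery scoring, with a machine-readable report.

Every stage is a plain function over the in-memory dataset so the CLI verbs
stay thin; ``run_pipeline`` chains them, logs row counts and seeds, writes
per-stage TSVs and a deterministic ``report.json`` (identical configs yield
byte-identical reports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import enrichment as enr
from . import regions as reg
from . import reversal as rev
from .simulate import (MARKS, MultiOmicDataset, SimConfig, generate_dataset,
                       read_dataset, write_dataset)

REPORT_SCHEMA_VERSION = "1.0"

log = logging.getLogger("rejuvenome")


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None
    input_dir: str | None = None
    thresholds: rev.CurationThresholds = field(default_factory=rev.CurationThresholds)
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "rejuvenome_out"

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of a SimConfig block or input_dir "
                             "must be provided")
        self.thresholds.validate()
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimConfig.from_dict(raw["sim"]) if "sim" in raw else None
        th = rev.CurationThresholds(**raw.get("thresholds", {}))
        return cls(sim=sim, input_dir=raw.get("input_dir"), thresholds=th,
                   n_perm=int(raw.get("n_perm", 1000)),
                   seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir", "rejuvenome_out"))


def setup_logging(out_dir: Path | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "pipeline.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        handlers=handlers, force=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> MultiOmicDataset:
    if cfg.input_dir is not None:
        log.info("loading dataset from %s", cfg.input_dir)
        return read_dataset(cfg.input_dir)
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed if cfg.sim.seed == 0 else cfg.sim.seed)
    log.info("simulating dataset (seed=%d, %d genes, %d peaks/mark, %d CpGs)",
             sim.seed, sim.n_genes, sim.n_peaks_per_mark, sim.n_cpgs)
    ds = generate_dataset(sim)
    write_dataset(ds, out / "dataset")
    return ds


def stage_differential(ds: MultiOmicDataset, out: Path) -> dict:
    """All six contrasts for every layer; protein via moderated t-tests."""
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    rna_f, rep = diff.filter_low_expression(ds.rna.counts, ds.samples)
    log.info("rna expression filter: kept %d dropped %d", rep["kept"], rep["dropped"])
    results["rna"] = diff.run_contrasts(rna_f, ds.samples)
    results["atac"] = diff.run_contrasts(ds.atac.counts, ds.samples)
    for mark in MARKS:
        results[mark] = diff.run_contrasts(ds.chip[mark].counts, ds.samples)
    prot_avg, prot_sheet = diff.average_techreps(ds.protein, ds.protein_samples)
    results["protein"] = {
        c: diff.moderated_linear_test(prot_avg, prot_sheet, c)
        for c in diff.CONTRASTS}
    for layer, by_contrast in results.items():
        for c, res in by_contrast.items():
            diff.diffresult_to_tsv(res, out / f"{layer}_{c}.tsv")
            log.info("differential %s/%s: %d features, %d at FDR<0.05",
                     layer, c, len(res), int((res["padj"] < 0.05).sum()))
    return results


def _der_regions(ds: MultiOmicDataset, mark: str, res: pd.DataFrame,
                 padj_cut: float = 0.05) -> reg.RegionSet:
    """Significant DERs of one mark as a direction-labelled RegionSet."""
    sig = res[(res["padj"] < padj_cut)]
    peaks = ds.chip[mark].regions.df.set_index("name")
    rows = []
    for fid, row in sig.iterrows():
        pk = peaks.loc[fid]
        direction = "up" if row["log2fc"] > 0 else "down"
        rows.append((pk["chrom"], pk["start"], pk["end"], f"{fid}|{direction}"))
    if not rows:
        return reg.RegionSet.from_tuples([], ds.layout.chrom_sizes)
    return reg.RegionSet.from_tuples(rows, ds.layout.chrom_sizes)


def stage_domains(ds: MultiOmicDataset, results: dict, out: Path) -> dict:
    """Bivalent domains from consensus peaks; switch domains from the aging
    DER directions of H3K27me3 and H3K9me3."""
    out.mkdir(parents=True, exist_ok=True)
    k4 = reg.consensus_peaks([ds.chip["H3K4me3"].regions])
    k27 = reg.consensus_peaks([ds.chip["H3K27me3"].regions])
    bivalent = reg.define_bivalent(k4, k27)
    k27_ders = _der_regions(ds, "H3K27me3", results["H3K27me3"]["aging_all_adj_env"])
    k9_ders = _der_regions(ds, "H3K9me3", results["H3K9me3"]["aging_all_adj_env"])
    domains, summary = reg.detect_switch_domains(k27_ders, k9_ders)
    log.info("domains: %d bivalent, %d switch (mean %.0f bp)",
             len(bivalent), summary["count"], summary["mean_length_bp"])
    reg.write_bed(bivalent, out / "bivalent_domains.bed")
    if domains:
        sw = reg.RegionSet.from_tuples(
            [(d.chrom, d.start, d.end, f"sw{i:03d}") for i, d in enumerate(domains)],
            ds.layout.chrom_sizes)
        reg.write_bed(sw, out / "switch_domains.bed")
    return {"bivalent": bivalent, "switch_domains": domains,
            "switch_summary": summary}


def stage_methylation(ds: MultiOmicDataset, domains: list, out: Path) -> dict:
    """Coverage-filter CpGs and measure the methylation trend over detected
    switch domains (old minus young mean beta per domain)."""
    out.mkdir(parents=True, exist_ok=True)
    filt = diff.filter_cpgs(ds.methylation)
    global_mean = float(filt["beta"].mean())
    log.info("methylation: %d CpG observations kept, global mean beta %.3f",
             len(filt), global_mean)
    result = {"global_mean_beta": global_mean, "n_domains": len(domains),
              "fraction_increased": None, "n_excluded": 0}
    if domains:
        dom_rs = reg.RegionSet.from_tuples(
            [(d.chrom, d.start, d.end, f"sw{i:03d}") for i, d in enumerate(domains)],
            ds.layout.chrom_sizes)
        per_region, empty = diff.region_methylation(filt, dom_rs)
        old_cols = ds.samples.loc[ds.samples["age"] == "old", "sample"]
        young_cols = ds.samples.loc[ds.samples["age"] == "young", "sample"]
        mean_old = per_region[list(old_cols)].mean(axis=1)
        mean_young = per_region[list(young_cols)].mean(axis=1)
        frac, n_excl = reg.switch_methylation_trend(mean_old.to_numpy(),
                                                    mean_young.to_numpy())
        per_region.to_csv(out / "switch_domain_methylation.tsv", sep="\t")
        result.update({"fraction_increased": frac, "n_excluded": n_excl})
        log.info("switch methylation trend: %.3f increased (%d domains, %d excluded)",
                 frac if frac == frac else float("nan"), len(domains), n_excl)
    return result


def stage_curation(ds: MultiOmicDataset, results: dict,
                   th: rev.CurationThresholds, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    curated: dict = {}
    for layer in ["rna", "protein"]:
        r = results[layer]
        reversed_set = rev.curate_reversal(
            r["aging_all_adj_env"], r["ee_young"], r["ee_old"], th, layer=layer)
        reju_set = rev.curate_rejuvenation(
            r["oc_vs_rest"], r["ee_young"], th, reversal_set=reversed_set,
            layer=layer)
        curated[layer] = {"reversed": reversed_set, "old_rejuvenated": reju_set}
        pd.concat([reversed_set, reju_set], ignore_index=True).to_csv(
            out / f"{layer}_curated.tsv", sep="\t", index=False)
        log.info("curation %s: %d reversed, %d old-rejuvenated",
                 layer, len(reversed_set), len(reju_set))
    for mark in MARKS:
        r = results[mark]
        reju = rev.curate_reju_regions(r["oc_vs_rest"], r["ee_old"],
                                       r["ee_young"], th, layer=mark)
        curated[mark] = {"old_rejuvenated": reju}
        reju.to_csv(out / f"{mark}_reju_regions.tsv", sep="\t", index=False)
        log.info("curation %s: %d rejuvenated regions", mark, len(reju))
    curated["multiomic_consistent"] = rev.consistent_multiomic(
        results["rna"]["aging_all_adj_env"], results["protein"]["aging_all_adj_env"],
        results["rna"]["ee_all_adj_age"], results["protein"]["ee_all_adj_age"])
    return curated


def stage_enrichment(ds: MultiOmicDataset, results: dict, curated: dict,
                     n_perm: int, seed: int, out: Path) -> pd.DataFrame:
    """The intersection battery: aging-vs-EE DEG overlap (gene permutation),
    aging K27-up x K9-down region test over the masked genome, and
    rejuvenated-region x rejuvenated-gene resampling."""
    out.mkdir(parents=True, exist_ok=True)
    battery: list[enr.EnrichmentResult] = []
    rna = results["rna"]
    universe = list(rna["aging_all_adj_env"].index)
    aging_degs = set(rna["aging_all_adj_env"].query("padj < 0.05").index)
    ee_degs = set(rna["ee_all_adj_age"].query("padj < 0.05").index)
    if aging_degs and ee_degs:
        battery.append(enr.permutation_gene_test(
            aging_degs, ee_degs, universe, n_perm, seed,
            comparison="aging_degs_x_ee_degs"))
    k27_up = _der_regions(ds, "H3K27me3", results["H3K27me3"]["aging_all_adj_env"])
    k9_down = _der_regions(ds, "H3K9me3", results["H3K9me3"]["aging_all_adj_env"])
    k27_up = reg.RegionSet(k27_up.df[k27_up.df["name"].str.endswith("|up")],
                           ds.layout.chrom_sizes) if len(k27_up) else k27_up
    k9_down = reg.RegionSet(k9_down.df[k9_down.df["name"].str.endswith("|down")],
                            ds.layout.chrom_sizes) if len(k9_down) else k9_down
    if len(k27_up) and len(k9_down):
        genome = reg.RegionSet.from_tuples(
            [(c, 0, l) for c, l in sorted(ds.layout.chrom_sizes.items())],
            ds.layout.chrom_sizes)
        background = reg.subtract_regions(genome, ds.layout.blacklist)
        battery.append(enr.permutation_region_test(
            k27_up, k9_down, background, n_perm, seed + 1,
            comparison="aging_k27me3_up_x_k9me3_down"))
    reju_genes = curated["rna"]["old_rejuvenated"]
    reju_k27 = curated["H3K27me3"]["old_rejuvenated"]
    if len(reju_genes) and len(reju_k27):
        peaks = ds.chip["H3K27me3"].regions
        pk = peaks.df.set_index("name")
        a_rows = [(pk.loc[f, "chrom"], pk.loc[f, "start"], pk.loc[f, "end"], f)
                  for f in reju_k27["feature_id"]]
        a = reg.RegionSet.from_tuples(a_rows, ds.layout.chrom_sizes)
        genes = ds.layout.genes.df.set_index("name")
        b_rows = [(genes.loc[g, "chrom"], genes.loc[g, "start"],
                   genes.loc[g, "end"], g)
                  for g in reju_genes["feature_id"] if g in genes.index]
        if b_rows:
            b = reg.RegionSet.from_tuples(b_rows, ds.layout.chrom_sizes)
            battery.append(enr.resample_region_test(
                a, b, peaks, n_perm, seed + 2,
                comparison="reju_k27me3_ders_x_reju_deg_bodies"))
    table = enr.enrichment_table(battery, family="pipeline_battery")
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for r in battery:
        log.info("enrichment %s: obs=%d null=%.2f p=%.4g FE=%.2f",
                 r.comparison, r.observed, r.null_mean, r.empirical_p,
                 r.fold_enrichment)
    return table


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _set_metrics(pred: set, truth: set) -> dict:
    tp = len(pred & truth)
    metrics = {
        "n_pred": len(pred), "n_truth": len(truth), "tp": tp,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(pred) if pred else float("nan"),
        "fdr": 1.0 - tp / len(pred) if pred else float("nan"),
        "jaccard": tp / len(pred | truth) if (pred | truth) else float("nan"),
    }
    return metrics


def _reciprocal_match(detected, planted, min_frac: float = 0.5
                      ) -> tuple[int, int, int]:
    """(planted blocks hit, reciprocal-50% matches, detections outside).

    A planted block is *hit* when >=1 detected domain overlaps it by >=1 bp
    (detected domains are merged DER intersections, typically much shorter
    than the planted block).  A *reciprocal match* additionally requires the
    overlap to cover >=min_frac of both intervals.  A detection is 'outside'
    when it overlaps no planted block at all.
    """
    hit, matched = set(), set()
    outside = 0
    pl = planted.df[["chrom", "start", "end"]].to_numpy(dtype=object)
    for d in detected:
        any_overlap = False
        for i, (c, s, e) in enumerate(pl):
            ov = min(d.end, e) - max(d.start, s)
            if c == d.chrom and ov > 0:
                any_overlap = True
                hit.add(i)
                if ov >= min_frac * (d.end - d.start) and ov >= min_frac * (e - s):
                    matched.add(i)
        if not any_overlap:
            outside += 1
    return len(hit), len(matched), outside


def evaluate_recovery(ds: MultiOmicDataset, results: dict, curated: dict,
                      domains: dict, meth: dict) -> dict:
    """Score the pipeline output against the planted TruthTable."""
    truth = ds.truth
    report: dict = {"layers": {}}
    for layer, aging_key in (("rna", "aging_all_adj_env"),
                             ("protein", "aging_all_adj_env")):
        t = truth[truth["layer"] == layer]
        res = results[layer][aging_key]
        pred = set(res.query("padj < 0.05").index)
        true_aging = set(t.loc[t["aging_class"] != "null", "feature_id"])
        layer_rep = {"aging": _set_metrics(pred, true_aging)}
        cur = curated.get(layer, {})
        if "reversed" in cur:
            layer_rep["reversed"] = _set_metrics(
                set(cur["reversed"]["feature_id"]),
                set(t.loc[t["ee_class"] == "reversed", "feature_id"]))
        if "old_rejuvenated" in cur:
            layer_rep["old_rejuvenated"] = _set_metrics(
                set(cur["old_rejuvenated"]["feature_id"]),
                set(t.loc[t["ee_class"] == "old_rejuvenated", "feature_id"]))
        nulls = set(t.loc[t["aging_class"] == "null", "feature_id"]) & set(res.index)
        null_p = res.loc[sorted(nulls), "p"].dropna()
        layer_rep["null_p_lt_05"] = float((null_p < 0.05).mean()) if len(null_p) else float("nan")
        report["layers"][layer] = layer_rep
    for mark in MARKS:
        t = truth[truth["layer"] == mark]
        res = results[mark]["aging_all_adj_env"]
        pred = set(res.query("padj < 0.05").index)
        true_aging = set(t.loc[t["aging_class"] != "null", "feature_id"])
        mark_rep = {"aging": _set_metrics(pred, true_aging)}
        if mark in curated:
            mark_rep["old_rejuvenated"] = _set_metrics(
                set(curated[mark]["old_rejuvenated"]["feature_id"]),
                set(t.loc[t["ee_class"] == "old_rejuvenated", "feature_id"]))
        report["layers"][mark] = mark_rep
    detected = domains["switch_domains"]
    hit, matched, outside = _reciprocal_match(detected, ds.switch_domains)
    report["switch_domains"] = {
        "n_planted": len(ds.switch_domains), "n_detected": len(detected),
        "n_planted_hit": hit, "n_reciprocal_matched": matched,
        "n_outside_planted": outside,
        "sensitivity": hit / len(ds.switch_domains) if len(ds.switch_domains)
        else float("nan"),
        "mean_length_bp": domains["switch_summary"]["mean_length_bp"],
    }
    report["bivalent_domains"] = {
        "n_planted": len(ds.bivalent_domains),
        "n_detected_overlapping_planted": enr.overlap_statistic(
            ds.bivalent_domains, domains["bivalent"]),
    }
    report["methylation"] = {
        "global_mean_beta": meth["global_mean_beta"],
        "switch_trend_fraction_increased": meth["fraction_increased"],
        "planted_fraction_increased": ds.config.switch_meth_frac,
    }
    return report


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write ``report.json``; returns the report dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    def _run(name, fn, *args, **kwargs):
        try:
            log.info("stage %s: start", name)
            res = fn(*args, **kwargs)
            stages.append(name)
            return res
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageFailure(name, exc) from exc

    ds = _run("simulate", stage_simulate, cfg, out)
    results = _run("differential", stage_differential, ds, out / "diff")
    domains = _run("domains", stage_domains, ds, results, out / "domains")
    meth = _run("methylation", stage_methylation, ds, domains["switch_domains"],
                out / "domains")
    curated = _run("curation", stage_curation, ds, results, cfg.thresholds,
                   out / "curate")
    enrich = _run("enrichment", stage_enrichment, ds, results, curated,
                  cfg.n_perm, cfg.seed, out / "enrich")
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "config": cfg.sim.to_dict() if cfg.sim is not None else
        {"input_dir": cfg.input_dir},
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "stages": stages,
        "curation_sizes": {
            layer: {cls: int(len(v)) for cls, v in sets.items()}
            for layer, sets in curated.items() if isinstance(sets, dict)},
        "multiomic_consistent_genes": curated["multiomic_consistent"],
        "enrichment": enrich.to_dict("records"),
        "switch_summary": domains["switch_summary"],
        "methylation": meth,
    }
    if cfg.input_dir is None:  # synthetic run: score against the truth
        recovery = _run("recovery", evaluate_recovery, ds, results, curated,
                        domains, meth)
        report["recovery"] = recovery
        validate_report(recovery)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    log.info("report written to %s", out / "report.json")
    return report


def validate_report(recovery: dict) -> None:
    """Check that every recovery metric lies in [0, 1] (NaN allowed)."""
    for layer, rep in recovery.get("layers", {}).items():
        for cls, metrics in rep.items():
            if not isinstance(metrics, dict):
                continue
            for key in ("sensitivity", "precision", "fdr", "jaccard"):
                v = metrics.get(key)
                if v is not None and v == v and not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"recovery metric out of range: {layer}/{cls}/{key}={v}")
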