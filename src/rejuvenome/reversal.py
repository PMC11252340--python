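"""Curation of enrichment-reversed and old-rejuvenated features.

Two complementary rule sets identify features whose aging alterations are
counteracted by environmental enrichment (EE):

* **reversed** — significantly aging-altered features (FDR < 0.05,
  |log2FC| > 0.25) whose EE fold change has the opposite sign, with
  |log2FC| > 0.25, in BOTH the young and the old EE contrasts;
* **old_rejuvenated** — features where old-control samples differ from all
  other groups (OC vs YC+YE+OE, FDR < 0.05, |log2FC| > 0.25) while EE shows
  no evidence of an effect in the young (unadjusted p >= 0.05); features
  already curated as reversed are excluded, so the two sets are disjoint.

Direction labels follow the convention that "down" means the rejuvenation
brings the level back down (the feature was up in aging / old-control), and
"up" the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CurationThresholds:
    padj_cut: float = 0.05
    lfc_cut: float = 0.25
    ee_young_null_p: float = 0.05

    def validate(self) -> None:
        if not (0 < self.padj_cut < 1 and 0 < self.ee_young_null_p < 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if self.lfc_cut <= 0:
            raise ValueError("lfc_cut must be positive")


REVERSAL_COLUMNS = ["feature_id", "layer", "class", "direction", "aging_lfc",
                    "ee_young_lfc", "ee_old_lfc", "oc_vs_rest_lfc"]


def _require(res: pd.DataFrame | None, name: str) -> pd.DataFrame:
    if res is None:
        raise ValueError(f"missing contrast result: {name}")
    return res


def curate_reversal(aging: pd.DataFrame, ee_young: pd.DataFrame,
                    ee_old: pd.DataFrame, th: CurationThresholds | None = None,
                    layer: str = "rna") -> pd.DataFrame:
    """EE-reversed features: significant aging change opposed by EE in both
    age groups (sign-opposite log2FC above the magnitude cut)."""
    th = th or CurationThresholds()
    th.validate()
    aging = _require(aging, "aging")
    ee_young = _require(ee_young, "ee_young")
    ee_old = _require(ee_old, "ee_old")
    idx = aging.index.intersection(ee_young.index).intersection(ee_old.index)
    a = aging.loc[idx]
    ey = ee_young.loc[idx]
    eo = ee_old.loc[idx]
    sig = (a["padj"] < th.padj_cut) & (a["log2fc"].abs() > th.lfc_cut)
    opp_young = (np.sign(ey["log2fc"]) == -np.sign(a["log2fc"])) & \
                (ey["log2fc"].abs() > th.lfc_cut)
    opp_old = (np.sign(eo["log2fc"]) == -np.sign(a["log2fc"])) & \
              (eo["log2fc"].abs() > th.lfc_cut)
    keep = sig & opp_young & opp_old
    sel = idx[keep.to_numpy(dtype=bool)]
    out = pd.DataFrame({
        "feature_id": sel,
        "layer": layer,
        "class": "reversed",
        "direction": np.where(a.loc[sel, "log2fc"] > 0, "down", "up"),
        "aging_lfc": a.loc[sel, "log2fc"].to_numpy(),
        "ee_young_lfc": ey.loc[sel, "log2fc"].to_numpy(),
        "ee_old_lfc": eo.loc[sel, "log2fc"].to_numpy(),
        "oc_vs_rest_lfc": np.nan,
    })
    return out.reset_index(drop=True)


def curate_rejuvenation(oc_vs_rest: pd.DataFrame, ee_young: pd.DataFrame,
                        th: CurationThresholds | None = None,
                        reversal_set: pd.DataFrame | None = None,
                        layer: str = "rna") -> pd.DataFrame:
    """Old-rejuvenated features: OC differs from all other groups while EE is
    null in the young; disjoint from the reversal set."""
    th = th or CurationThresholds()
    th.validate()
    oc = _require(oc_vs_rest, "oc_vs_rest")
    ey = _require(ee_young, "ee_young")
    idx = oc.index.intersection(ey.index)
    o = oc.loc[idx]
    y = ey.loc[idx]
    keep = (o["padj"] < th.padj_cut) & (o["log2fc"].abs() > th.lfc_cut) & \
           (y["p"] >= th.ee_young_null_p)
    sel = idx[keep.to_numpy(dtype=bool)]
    if reversal_set is not None and len(reversal_set):
        sel = sel[~sel.isin(set(reversal_set["feature_id"]))]
    out = pd.DataFrame({
        "feature_id": sel,
        "layer": layer,
        "class": "old_rejuvenated",
        "direction": np.where(o.loc[sel, "log2fc"] > 0, "down", "up"),
        "aging_lfc": np.nan,
        "ee_young_lfc": y.loc[sel, "log2fc"].to_numpy(),
        "ee_old_lfc": np.nan,
        "oc_vs_rest_lfc": o.loc[sel, "log2fc"].to_numpy(),
    })
    return out.reset_index(drop=True)


def curate_reju_regions(oc_vs_rest: pd.DataFrame, ee_old: pd.DataFrame,
                        ee_young: pd.DataFrame,
                        th: CurationThresholds | None = None,
                        layer: str = "chip") -> pd.DataFrame:
    """Old-rejuvenated chromatin regions for one histone mark: OC-vs-rest
    significant, an EE change of magnitude above the cut in the old, and no
    EE evidence in the young."""
    th = th or CurationThresholds()
    th.validate()
    oc = _require(oc_vs_rest, "oc_vs_rest")
    eo = _require(ee_old, "ee_old")
    ey = _require(ee_young, "ee_young")
    idx = oc.index.intersection(eo.index).intersection(ey.index)
    o, e_o, e_y = oc.loc[idx], eo.loc[idx], ey.loc[idx]
    keep = (o["padj"] < th.padj_cut) & (e_o["log2fc"].abs() > th.lfc_cut) & \
           (e_y["p"] >= th.ee_young_null_p)
    sel = idx[keep.to_numpy(dtype=bool)]
    out = pd.DataFrame({
        "feature_id": sel,
        "layer": layer,
        "class": "old_rejuvenated",
        "direction": np.where(o.loc[sel, "log2fc"] > 0, "down", "up"),
        "aging_lfc": np.nan,
        "ee_young_lfc": e_y.loc[sel, "log2fc"].to_numpy(),
        "ee_old_lfc": e_o.loc[sel, "log2fc"].to_numpy(),
        "oc_vs_rest_lfc": o.loc[sel, "log2fc"].to_numpy(),
    })
    return out.reset_index(drop=True)


def consistent_multiomic(aging_rna: pd.DataFrame, aging_prot: pd.DataFrame,
                         ee_rna: pd.DataFrame, ee_prot: pd.DataFrame,
                         p_cut: float = 0.05) -> list[str]:
    """Genes with concordant RNA and protein aging changes (unadjusted
    p < 0.05, equal sign) whose EE change is sign-opposite in both layers.

    The EE requirement is sign-only (no magnitude threshold).
    """
    shared = aging_rna.index.intersection(aging_prot.index)
    if len(shared) == 0:
        raise ValueError("RNA and protein results share no genes")
    shared = shared.intersection(ee_rna.index).intersection(ee_prot.index)
    ar, ap = aging_rna.loc[shared], aging_prot.loc[shared]
    er, ep = ee_rna.loc[shared], ee_prot.loc[shared]
    sig = (ar["p"] < p_cut) & (ap["p"] < p_cut)
    same = np.sign(ar["log2fc"]) == np.sign(ap["log2fc"])
    opp = (np.sign(er["log2fc"]) == -np.sign(ar["log2fc"])) & \
          (np.sign(ep["log2fc"]) == -np.sign(ap["log2fc"]))
    return sorted(shared[(sig & same & opp).to_numpy(dtype=bool)])


# ---------------------------------------------------------------------------
# Distribution-shift statistics
# ---------------------------------------------------------------------------

def _ranksum(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
             ) -> tuple[float, float]:
    """Wilcoxon rank-sum: exact enumeration for small tie-free samples,
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = (len(x) <= 25 and len(y) <= 25
             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def ee_shift_test(aging_up_ee_lfc, aging_down_ee_lfc,
                  alternative: str = "two-sided") -> dict:
    """Compare the EE fold-change distributions of aging-up vs aging-down
    features (Wilcoxon rank-sum); EE reversal shows as a negative median for
    the aging-up set and a positive one for the aging-down set."""
    x = np.asarray(aging_up_ee_lfc, float)
    y = np.asarray(aging_down_ee_lfc, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >=3 features per side")
    stat, p = _ranksum(x, y, alternative)
    return {"stat": stat, "p": p,
            "median_up_set": float(np.median(x)),
            "median_down_set": float(np.median(y))}


def ee_signrank_test(ee_lfc, alternative: str = "two-sided") -> dict:
    """One-sample Wilcoxon signed-rank of EE fold changes against zero."""
    x = np.asarray(ee_lfc, float)
    x = x[x != 0]
    if len(x) < 3:
        raise ValueError("need >=3 nonzero values")
    mode = "exact" if len(x) <= 25 else "approx"
    res = stats.wilcoxon(x, alternative=alternative, method=mode)
    return {"stat": float(res.statistic), "p": float(res.pvalue),
            "median": float(np.median(x))}


def reversal_strength_compare(reversal_set: pd.DataFrame,
                              ee_young: pd.DataFrame,
                              ee_old: pd.DataFrame) -> dict:
    """Within the reversal set, compare |EE log2FC| magnitudes between young
    and old (Wilcoxon rank-sum)."""
    ids = [f for f in reversal_set["feature_id"]
           if f in ee_young.index and f in ee_old.index]
    if len(ids) < 3:
        raise ValueError("reversal set too small to compare (need >=3)")
    ya = ee_young.loc[ids, "log2fc"].abs().to_numpy()
    oa = ee_old.loc[ids, "log2fc"].abs().to_numpy()
    stat, p = _ranksum(ya, oa)
    return {"stat": stat, "p": p,
            "median_young_abs": float(np.median(ya)),
            "median_old_abs": float(np.median(oa))}
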