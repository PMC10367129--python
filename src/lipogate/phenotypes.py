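"""Preset classification cascades for liposome phenotyping.

Implements the sequential gating strategies of the analysis workflow:

* liposome identification (size/shape, intensity-vs-area junk rejection,
  focus, texture-based aggregate rejection),
* morphometrics (spherical vs nonspherical; unilamellar vs multilamellar;
  rod vs doublet),
* reporter modules: gene expression (lumen intensity), DNA replication
  (negative / homogeneous / condensate blob), cytoskeletal filaments,
  membrane relocalization (bright-detail colocalization), and
  negative-control-thresholded lipid synthesis (PS),

plus population statistics. Scale-free cut-offs (8 um^2 area, 0.4 aspect
ratio) are fixed; scale-dependent cut-offs come from the calibrated preset
(see `lipogate.calibration`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import default_presets, spec_to_gate
from .gating import (
    GatingResult,
    Pipeline,
    ThresholdGate,
    evaluate_gate,
    run_pipeline,
    threshold_from_negative,
)

__all__ = [
    "identify_liposomes",
    "classify_morphology",
    "classify_expression",
    "classify_replication",
    "classify_filaments",
    "classify_relocalization",
    "classify_ps",
    "population_summary",
    "build_identify_pipeline",
    "with_derived_features",
]

#: Scale-free identification cut-offs, in the units of the feature table.
AREA_CUT_UM2 = 8.0
ASPECT_RATIO_CUT = 0.4


def with_derived_features(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns used by preset gates (log-intensity axes)."""
    out = table.copy()
    for ch in ("membrane", "reporter"):
        col = f"intensity_{ch}"
        if col in out.columns and f"log_{col}" not in out.columns:
            out[f"log_{col}"] = np.log10(out[col].astype(float) + 1.0)
    return out


def build_identify_pipeline(presets: dict | None = None) -> Pipeline:
    """The liposome-identification cascade as an ordered gate pipeline."""
    p = presets or default_presets()
    ident = p["identify"]
    stages = (
        ("area", ThresholdGate(name="area", feature="area", lo=AREA_CUT_UM2)),
        ("aspect_ratio",
         ThresholdGate(name="aspect_ratio", feature="aspect_ratio",
                       lo=ASPECT_RATIO_CUT)),
        ("not_debris",
         spec_to_gate(ident["debris_region"], "not_debris", inside=False)),
        ("not_dense_aggregate",
         spec_to_gate(ident["aggregate_region"], "not_dense_aggregate",
                      inside=False)),
        ("in_focus", spec_to_gate(ident["focus"], "in_focus")),
        ("homogeneous", spec_to_gate(ident["homogeneity"], "homogeneous")),
        ("not_texture_aggregate",
         spec_to_gate(ident["texture_aggregate_region"],
                      "not_texture_aggregate", inside=False)),
    )
    return Pipeline(name="identify", stages=stages)


#: Which identification label a failure at each stage implies.
_STAGE_FAIL_LABEL = {
    "aspect_ratio": "aggregate",
    "not_debris": "debris",
    "not_dense_aggregate": "aggregate",
    "in_focus": "out_of_focus",
    "homogeneous": "aggregate",
    "not_texture_aggregate": "aggregate",
}


def identify_liposomes(
    table: pd.DataFrame, presets: dict | None = None
) -> tuple[pd.DataFrame, GatingResult]:
    """Run the identification cascade and label every event.

    Returns a labels frame (column ``identification`` in {good_liposome,
    debris, aggregate, out_of_focus, rejected}) plus the per-stage gating
    accounting. Events with empty masks or undefined features are
    ``rejected``, never silently dropped.
    """
    tbl = with_derived_features(table)
    pipeline = build_identify_pipeline(presets)
    result = run_pipeline(tbl, pipeline)

    ident = pd.Series("good_liposome", index=tbl.index, name="identification")
    alive = np.ones(len(tbl), dtype=bool)
    area = tbl["area"].to_numpy(dtype=float)
    for stage_name, _gate in pipeline.stages:
        passed = result.membership[stage_name].to_numpy()
        failed_here = alive & ~passed
        if stage_name == "area":
            small = failed_here & (area <= AREA_CUT_UM2)
            ident.iloc[np.nonzero(small)[0]] = "debris"
            ident.iloc[np.nonzero(failed_here & ~small)[0]] = "rejected"
        else:
            ident.iloc[np.nonzero(failed_here)[0]] = _STAGE_FAIL_LABEL[stage_name]
        alive = alive & passed
    if "mask_ok" in tbl.columns:
        ident[tbl["mask_ok"] == 0] = "rejected"
    labels = ident.to_frame()
    return labels, result


def _good(labels: pd.DataFrame) -> pd.Series:
    return labels["identification"] == "good_liposome"


def classify_morphology(
    table: pd.DataFrame, labels: pd.DataFrame, presets: dict | None = None
) -> pd.DataFrame:
    """Split good liposomes into morphological classes.

    Spherical vs nonspherical on the calibrated circularity cut; spherical
    into unilamellar vs multilamellar in the (compactness, max pixel)
    plane; nonspherical into rod vs doublet in the (H-entropy std,
    H-correlation std) plane. Events matched by neither region keep an
    explicit ``unclassified`` / ``nonspherical_other`` label.
    """
    p = presets or default_presets()
    morph = p["morphology"]
    out = labels.copy()
    good = _good(out)

    spherical = evaluate_gate(table, spec_to_gate(morph["circularity"], "circ"))
    in_multi = evaluate_gate(
        table, spec_to_gate(morph["multilamellar_region"], "multi"))
    in_uni = evaluate_gate(
        table, spec_to_gate(morph["unilamellar_region"], "uni"))
    in_rod = evaluate_gate(table, spec_to_gate(morph["rod_region"], "rod"))
    in_doublet = evaluate_gate(
        table, spec_to_gate(morph["doublet_region"], "doublet"))

    label = np.full(len(table), "unclassified", dtype=object)
    g = good.to_numpy()
    sph = g & spherical
    non = g & ~spherical
    label[sph & in_multi] = "spherical_multilamellar"
    label[sph & ~in_multi & in_uni] = "spherical_unilamellar"
    label[non] = "nonspherical_other"
    label[non & in_rod] = "rod"
    label[non & ~in_rod & in_doublet] = "doublet"
    label[~g] = "unclassified"
    out["morphology"] = label
    return out


def classify_expression(
    table: pd.DataFrame,
    labels: pd.DataFrame,
    threshold: float | None = None,
    presets: dict | None = None,
) -> pd.DataFrame:
    """Label good liposomes expressing / nonexpressing on reporter intensity."""
    if threshold is None:
        p = presets or default_presets()
        threshold = float(p["expression"]["intensity"]["threshold"])
    out = labels.copy()
    good = _good(out).to_numpy()
    x = table["intensity_reporter"].to_numpy(dtype=float)
    label = np.full(len(table), "not_evaluated", dtype=object)
    label[good & (x > threshold)] = "expressing"
    label[good & ~(x > threshold)] = "nonexpressing"
    out["expression"] = label
    return out


def expression_stats(table: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Size distributions of expressing vs nonexpressing subpopulations and
    the intensity-area correlation among expressing liposomes."""
    stats = {}
    for grp in ("expressing", "nonexpressing"):
        sel = labels["expression"] == grp
        areas = table.loc[sel, "area"].astype(float)
        stats[grp] = {
            "n": int(sel.sum()),
            "area_mean": float(areas.mean()) if sel.any() else np.nan,
            "area_sd": float(areas.std()) if sel.any() else np.nan,
        }
    sel = labels["expression"] == "expressing"
    if sel.sum() >= 3:
        stats["intensity_area_pearson_r"] = float(
            np.corrcoef(
                table.loc[sel, "area"].astype(float),
                table.loc[sel, "intensity_reporter"].astype(float),
            )[0, 1]
        )
    else:
        stats["intensity_area_pearson_r"] = np.nan
    return stats


def classify_replication(
    table: pd.DataFrame, labels: pd.DataFrame, presets: dict | None = None
) -> pd.DataFrame:
    """Three-class DNA-replication call: negative, homogeneous, blob.

    Reporter intensity below the calibrated cut is negative; above-cut
    events with high std dev / low H-homogeneity mean (condensed punctum)
    are blob, the rest homogeneous.
    """
    p = presets or default_presets()
    repl = p["replication"]
    out = labels.copy()
    good = _good(out).to_numpy()
    above = evaluate_gate(table, spec_to_gate(repl["intensity"], "repl_int"))
    in_blob = evaluate_gate(table, spec_to_gate(repl["blob_region"], "blob"))
    label = np.full(len(table), "not_evaluated", dtype=object)
    label[good & ~above] = "negative"
    label[good & above & in_blob] = "blob"
    label[good & above & ~in_blob] = "homogeneous"
    out["replication"] = label
    return out


def classify_filaments(
    table: pd.DataFrame, labels: pd.DataFrame, presets: dict | None = None
) -> pd.DataFrame:
    """Filament call in the (std dev, contrast) plane above the intensity cut."""
    p = presets or default_presets()
    fil = p["filaments"]
    out = labels.copy()
    good = _good(out).to_numpy()
    above = evaluate_gate(table, spec_to_gate(fil["intensity"], "fil_int"))
    in_fil = evaluate_gate(table, spec_to_gate(fil["filament_region"], "fil"))
    label = np.full(len(table), "not_evaluated", dtype=object)
    label[good & ~above] = "below_intensity"
    label[good & above & in_fil] = "filament"
    label[good & above & ~in_fil] = "no_filament"
    out["filament"] = label
    return out


def classify_relocalization(
    table: pd.DataFrame, labels: pd.DataFrame, presets: dict | None = None
) -> pd.DataFrame:
    """Membrane-relocalization call via bright-detail similarity.

    An extra membrane-texture gate (H-correlation std vs H-contrast std)
    first excludes events with internal membrane structure; the remainder
    are active (membrane-localized reporter) when the bright-detail
    similarity of membrane and reporter channels exceeds its calibrated
    cut, else inactive (lumen-localized).
    """
    p = presets or default_presets()
    reloc = p["relocalization"]
    out = labels.copy()
    good = _good(out).to_numpy()
    excluded = evaluate_gate(
        table, spec_to_gate(reloc["lamellarity_exclusion_region"], "lam"))
    above = evaluate_gate(table, spec_to_gate(reloc["bds"], "bds"))
    label = np.full(len(table), "not_evaluated", dtype=object)
    label[good & excluded] = "excluded_lamellarity"
    label[good & ~excluded & above] = "active"
    label[good & ~excluded & ~above] = "inactive"
    out["relocalization"] = label
    return out


def classify_ps(
    positive_table: pd.DataFrame,
    negative_table: pd.DataFrame,
    labels: pd.DataFrame,
    max_fpr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Negative-control-thresholded PS-synthesis call.

    The positivity cut is the empirical (1 - max_fpr) quantile of the
    negative sample's membrane-probe (reporter) intensity, so at most
    ``max_fpr`` of negatives would be called positive.
    """
    if len(negative_table) == 0:
        raise ValueError("negative control table must be nonempty")
    neg_vals = negative_table["intensity_reporter"].to_numpy(dtype=float)
    neg_vals = neg_vals[np.isfinite(neg_vals)]
    if neg_vals.size == 0:
        raise ValueError("negative control has no defined reporter intensity")
    threshold = threshold_from_negative(neg_vals, max_fpr)

    out = labels.copy()
    good = _good(out).to_numpy()
    x = positive_table["intensity_reporter"].to_numpy(dtype=float)
    label = np.full(len(positive_table), "not_evaluated", dtype=object)
    label[good & (x > threshold)] = "ps_positive"
    label[good & ~(x > threshold)] = "ps_negative"
    out["ps"] = label
    info = {
        "threshold": float(threshold),
        "max_fpr": float(max_fpr),
        "negative_fpr": float((neg_vals > threshold).mean()),
        "n_negative": int(neg_vals.size),
    }
    return out, info


def population_summary(
    labels: pd.DataFrame,
    table: pd.DataFrame,
    size_cut_um: float = 10.0,
    presets: dict | None = None,
) -> dict:
    """Counts/fractions at every labelled level plus size statistics.

    Fractions at each level sum to 1 over the labelled events of that
    level; diameter statistics (mean, sd, fraction below ``size_cut_um``)
    are reported for good liposomes overall and per morphology class.
    Mask-equivalent diameters are mapped to object diameters through the
    preset size calibration (fitted on reference spheres, the synthetic
    analogue of bead calibration) when available.
    """
    p = presets if presets is not None else default_presets()
    cal = p.get("size_calibration")
    if cal is not None:
        table = table.copy()
        table["diameter"] = (cal["slope"] * table["diameter"].astype(float)
                             + cal["intercept"])
    summary: dict = {"n_events": int(len(labels))}
    for level in ("identification", "morphology", "expression", "replication",
                  "filament", "relocalization", "ps"):
        if level not in labels.columns:
            continue
        col = labels[level]
        col = col[col != "not_evaluated"]
        counts = col.value_counts().to_dict()
        total = int(sum(counts.values()))
        summary[level] = {
            "counts": {str(k): int(v) for k, v in counts.items()},
            "fractions": {str(k): (v / total if total else 0.0)
                          for k, v in counts.items()},
        }

    good = _good(labels)
    diam = table.loc[good, "diameter"].astype(float).dropna()
    size = {
        "n": int(diam.size),
        "mean": float(diam.mean()) if diam.size else np.nan,
        "sd": float(diam.std()) if diam.size else np.nan,
        "fraction_below_cut": float((diam < size_cut_um).mean())
        if diam.size else np.nan,
        "cut_um": float(size_cut_um),
    }
    summary["diameter_good"] = size
    if "morphology" in labels.columns:
        per_class = {}
        for cls, grp in table.loc[good].groupby(labels.loc[good, "morphology"]):
            d = grp["diameter"].astype(float).dropna()
            per_class[str(cls)] = {
                "n": int(d.size),
                "mean": float(d.mean()) if d.size else np.nan,
                "sd": float(d.std()) if d.size else np.nan,
            }
        summary["diameter_by_morphology"] = per_class
    return summary
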