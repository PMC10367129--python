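"""Calibration of scale-dependent gate cut-offs on synthetic populations.

The gating cascades use two kinds of decision rules: 1D thresholds
(balanced-accuracy optimal cuts, see `lipogate.gating.calibrate_threshold`)
and 2D regions in a named feature-pair plane. The hand-drawn regions of an
interactive analysis are approximated here by polygons extracted from the
0.5-posterior contour of a quadratic discriminant fitted to labelled
synthetic training events. All calibrations are seed-fixed and stored in a
YAML preset that ships with the package; `scripts/calibrate_presets.py`
regenerates it.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import yaml
from skimage.measure import find_contours
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from .features import FeatureConfig, build_feature_table
from .gating import (
    RegionGate,
    ThresholdGate,
    calibrate_threshold,
)
from .synthetic import DEFAULT_OPTICS, PopulationComposition, sample_population

__all__ = [
    "calibrate_pair_gate",
    "build_presets",
    "save_presets",
    "load_presets",
    "default_presets",
]

DEFAULT_PRESET_SEED = 20513


def calibrate_pair_gate(
    table: pd.DataFrame,
    truth,
    x_feature: str,
    y_feature: str,
    positive_class,
    *,
    name: str,
    grid_n: int = 160,
    pad: float = 0.5,
    reg_param: float = 0.05,
    simplify: int = 4,
    max_negative_rate: float | None = None,
) -> RegionGate:
    """Polygonal region where the positive class dominates a feature plane.

    Fits a QDA to the two named features, evaluates the positive-class
    posterior on a padded grid, and traces the decision contour into
    closed polygons (marching squares on a zero-padded grid, so every
    contour closes). Membership of the returned gate is even-odd over the
    polygon list, which handles disjoint lobes and holes.

    ``max_negative_rate`` raises the posterior level above 0.5 until at
    most that fraction of the negative training class falls inside the
    region — used for rejection regions that must not consume the
    population of interest. The region may then be empty (gate matches
    nothing).
    """
    y = np.asarray(truth) == positive_class
    x1 = table[x_feature].to_numpy(dtype=float)
    x2 = table[y_feature].to_numpy(dtype=float)
    keep = np.isfinite(x1) & np.isfinite(x2)
    x1, x2, y = x1[keep], x2[keep], y[keep]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present for pair-gate calibration")
    X = np.column_stack([x1, x2])
    qda = QuadraticDiscriminantAnalysis(reg_param=reg_param, priors=[0.5, 0.5])
    qda.fit(X, y.astype(int))

    level = 0.5
    if max_negative_rate is not None:
        post_neg = qda.predict_proba(X[~y])[:, 1]
        level = max(level, float(np.quantile(post_neg, 1.0 - max_negative_rate))
                    + 1e-9)

    lo1, hi1 = x1.min(), x1.max()
    lo2, hi2 = x2.min(), x2.max()
    span1 = max(hi1 - lo1, 1e-9)
    span2 = max(hi2 - lo2, 1e-9)
    g1 = np.linspace(lo1 - pad * span1, hi1 + pad * span1, grid_n)
    g2 = np.linspace(lo2 - pad * span2, hi2 + pad * span2, grid_n)
    gx, gy = np.meshgrid(g1, g2, indexing="ij")
    post = qda.predict_proba(np.column_stack([gx.ravel(), gy.ravel()]))[:, 1]
    region = (post.reshape(grid_n, grid_n) >= level).astype(float)
    padded = np.pad(region, 1, constant_values=0.0)

    d1 = g1[1] - g1[0]
    d2 = g2[1] - g2[0]
    polygons = []
    for contour in find_contours(padded, 0.5):
        pts = contour[::simplify] if len(contour) > 3 * simplify else contour
        # padded index -> feature coordinates (index 1 maps to g[0])
        xs = g1[0] + (pts[:, 0] - 1.0) * d1
        ys = g2[0] + (pts[:, 1] - 1.0) * d2
        poly = tuple(zip(map(float, xs), map(float, ys)))
        if len(poly) >= 3:
            polygons.append(poly)
    if not polygons and max_negative_rate is None:
        raise ValueError(
            f"no decision region found for {positive_class!r} in "
            f"({x_feature}, {y_feature})"
        )
    return RegionGate(
        name=name,
        x_feature=x_feature,
        y_feature=y_feature,
        polygons=tuple(polygons),
    )


# ---------------------------------------------------------------------------
# preset construction
# ---------------------------------------------------------------------------

#: Seed-fixed training mixtures; equal class weights give every gate enough
#: examples of each side of its decision.
_TRAIN_N_PER_CLASS = 350


def _train_table(classes, seed, optics, n_per_class=_TRAIN_N_PER_CLASS,
                 config: FeatureConfig | None = None):
    comp = PopulationComposition(
        class_weights={c: 1.0 for c in classes},
        n_events=n_per_class * len(classes),
        seed=seed,
    )
    events, truth = sample_population(comp, optics)
    table = build_feature_table(events, config)
    return table, truth


def build_presets(
    seed: int = DEFAULT_PRESET_SEED,
    optics=DEFAULT_OPTICS,
    config: FeatureConfig | None = None,
) -> dict:
    """Calibrate every scale-dependent gate of the phenotype cascades.

    Returns a nested dict (pipeline -> stage -> gate spec) serializable
    with `save_presets`. Scale-free cut-offs (8 um^2 area, 0.4 aspect
    ratio) are fixed upstream and are not calibrated here.
    """
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("morph", "expr", "repl", "fil", "reloc")}

    presets: dict = {"meta": {"seed": int(seed)}}

    # --- identification + morphology (membrane channel) -------------------
    morph_classes = ("sphere", "multilamellar", "rod", "doublet",
                     "aggregate", "debris", "out_of_focus")
    table, truth_full = _train_table(morph_classes, seeds["morph"], optics,
                                     config=config)
    truth = truth_full["class_label"]
    liposome = truth.isin(["sphere", "multilamellar", "rod", "doublet"])

    # size calibration: mask-equivalent diameter carries a dilation + PSF
    # margin; fit the linear map to true diameter on the sphere class
    # (the synthetic analogue of instrument bead calibration)
    sph = truth == "sphere"
    d_mask = table.loc[sph, "diameter"].to_numpy(dtype=float)
    d_true = truth_full.loc[sph, "true_diameter"].to_numpy(dtype=float)
    ok = np.isfinite(d_mask)
    slope, intercept = np.polyfit(d_mask[ok], d_true[ok], 1)

    tbl = table.copy()
    tbl["log_intensity_membrane"] = np.log10(tbl["intensity_membrane"] + 1.0)

    debris_gate = calibrate_pair_gate(
        tbl[truth != "aggregate"], truth[truth != "aggregate"],
        "area", "log_intensity_membrane", "debris", name="debris_region",
        max_negative_rate=0.001,
    )
    aggregate_gate = calibrate_pair_gate(
        tbl[truth != "debris"], truth[truth != "debris"],
        "area", "log_intensity_membrane", "aggregate", name="aggregate_region",
        max_negative_rate=0.002,
    )
    focus_rows = truth.isin(["sphere", "multilamellar", "rod", "doublet",
                             "out_of_focus"])
    focus_cal = calibrate_threshold(
        table[focus_rows],
        np.where(truth[focus_rows] == "out_of_focus", "oof", "sharp"),
        "gradient_rms_membrane", "sharp",
    )
    homog_rows = truth.isin(["sphere", "multilamellar", "rod", "doublet",
                             "aggregate"])
    # the homogeneity cut must not consume good liposomes even when the
    # texture contrast with aggregates is weak, hence the recall floor
    homog_cal = calibrate_threshold(
        table[homog_rows],
        np.where(liposome[homog_rows], "lipo", "agg"),
        "h_homogeneity_mean_membrane", "lipo",
        min_positive_recall=0.995,
    )
    texture_gate = calibrate_pair_gate(
        table[homog_rows],
        np.where(liposome[homog_rows], "lipo", "agg"),
        "h_correlation_mean_membrane", "h_correlation_std_membrane", "agg",
        name="texture_aggregate_region", max_negative_rate=0.002,
    )

    presets["identify"] = {
        "debris_region": _gate_to_spec(debris_gate),
        "aggregate_region": _gate_to_spec(aggregate_gate),
        "focus": _threshold_spec(focus_cal),
        "homogeneity": _threshold_spec(homog_cal),
        "texture_aggregate_region": _gate_to_spec(texture_gate),
    }

    # --- morphology -------------------------------------------------------
    spherical = truth.isin(["sphere", "multilamellar"])
    shape_rows = truth.isin(["sphere", "multilamellar", "rod", "doublet"])
    circ_cal = calibrate_threshold(
        table[shape_rows],
        np.where(spherical[shape_rows], "spherical", "nonspherical"),
        "circularity", "spherical",
    )
    lam_rows = truth.isin(["sphere", "multilamellar"])
    multilam_gate = calibrate_pair_gate(
        table[lam_rows], truth[lam_rows],
        "compactness_membrane", "max_pixel_membrane", "multilamellar",
        name="multilamellar_region",
    )
    unilam_gate = calibrate_pair_gate(
        table[lam_rows], truth[lam_rows],
        "compactness_membrane", "max_pixel_membrane", "sphere",
        name="unilamellar_region",
    )
    rd_rows = truth.isin(["rod", "doublet"])
    rod_gate = calibrate_pair_gate(
        table[rd_rows], truth[rd_rows],
        "h_entropy_std_membrane", "h_correlation_std_membrane", "rod",
        name="rod_region",
    )
    doublet_gate = calibrate_pair_gate(
        table[rd_rows], truth[rd_rows],
        "h_entropy_std_membrane", "h_correlation_std_membrane", "doublet",
        name="doublet_region",
    )
    presets["morphology"] = {
        "circularity": _threshold_spec(circ_cal),
        "multilamellar_region": _gate_to_spec(multilam_gate),
        "unilamellar_region": _gate_to_spec(unilam_gate),
        "rod_region": _gate_to_spec(rod_gate),
        "doublet_region": _gate_to_spec(doublet_gate),
    }

    # --- unilamellarity gate for relocalization (membrane channel) --------
    reloc_quality_gate = calibrate_pair_gate(
        table[lam_rows], truth[lam_rows],
        "h_correlation_std_membrane", "h_contrast_std_membrane", "multilamellar",
        name="lamellarity_exclusion_region", max_negative_rate=0.005,
    )

    # --- expression -------------------------------------------------------
    etable, etruth = _train_table(("expressing", "nonexpressing"),
                                  seeds["expr"], optics, config=config)
    etruth = etruth["class_label"]
    expr_cal = calibrate_threshold(etable, etruth, "intensity_reporter",
                                   "expressing")
    presets["expression"] = {"intensity": _threshold_spec(expr_cal)}

    # --- replication ------------------------------------------------------
    rtable, rtruth = _train_table(
        ("repl_negative", "repl_homogeneous", "repl_blob"),
        seeds["repl"], optics, config=config)
    rtruth = rtruth["class_label"]
    pos = rtruth.isin(["repl_homogeneous", "repl_blob"])
    repl_int = calibrate_threshold(
        rtable, np.where(pos, "pos", "neg"), "intensity_reporter", "pos")
    blob_rows = pos
    blob_gate = calibrate_pair_gate(
        rtable[blob_rows], rtruth[blob_rows],
        "std_dev_reporter", "h_homogeneity_mean_reporter", "repl_blob",
        name="blob_region",
    )
    presets["replication"] = {
        "intensity": _threshold_spec(repl_int),
        "blob_region": _gate_to_spec(blob_gate),
    }

    # --- filaments --------------------------------------------------------
    ftable, ftruth = _train_table(
        ("filament_negative", "no_filament", "filament"),
        seeds["fil"], optics, config=config)
    ftruth = ftruth["class_label"]
    fpos = ftruth.isin(["no_filament", "filament"])
    fil_int = calibrate_threshold(
        ftable, np.where(fpos, "pos", "neg"), "intensity_reporter", "pos")
    fil_gate = calibrate_pair_gate(
        ftable[fpos], ftruth[fpos],
        "std_dev_reporter", "contrast_reporter", "filament",
        name="filament_region", max_negative_rate=0.02,
    )
    presets["filaments"] = {
        "intensity": _threshold_spec(fil_int),
        "filament_region": _gate_to_spec(fil_gate),
    }

    # --- relocalization ---------------------------------------------------
    mtable, mtruth = _train_table(("min_inactive", "min_active"),
                                  seeds["reloc"], optics, config=config)
    bds_cal = calibrate_threshold(mtable, mtruth["class_label"],
                                  "bds_r3_membrane_reporter", "min_active")
    presets["relocalization"] = {
        "lamellarity_exclusion_region": _gate_to_spec(reloc_quality_gate),
        "bds": _threshold_spec(bds_cal),
    }
    presets["size_calibration"] = {
        "slope": round(float(slope), 6),
        "intercept": round(float(intercept), 6),
    }
    return presets


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def _gate_to_spec(gate: RegionGate) -> dict:
    return {
        "type": "region",
        "x_feature": gate.x_feature,
        "y_feature": gate.y_feature,
        "inside": bool(gate.inside),
        "polygons": [
            [[round(float(x), 6), round(float(y), 6)] for x, y in poly]
            for poly in gate.polygons
        ],
    }


def _threshold_spec(cal) -> dict:
    return {
        "type": "threshold",
        "feature": cal.feature,
        "threshold": round(float(cal.threshold), 6),
        "positive_above": bool(cal.positive_above),
        "balanced_accuracy": round(float(cal.balanced_accuracy), 4),
    }


def spec_to_gate(spec: dict, name: str, *, inside: bool | None = None):
    """Rebuild a gate object from its preset dict."""
    if spec["type"] == "region":
        return RegionGate(
            name=name,
            x_feature=spec["x_feature"],
            y_feature=spec["y_feature"],
            polygons=tuple(
                tuple((float(x), float(y)) for x, y in poly)
                for poly in spec["polygons"]
            ),
            inside=spec["inside"] if inside is None else inside,
        )
    if spec["type"] == "threshold":
        if spec["positive_above"]:
            return ThresholdGate(name=name, feature=spec["feature"],
                                 lo=spec["threshold"])
        return ThresholdGate(name=name, feature=spec["feature"],
                             hi=spec["threshold"])
    raise ValueError(f"unknown gate spec type {spec['type']!r}")


def save_presets(presets: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(presets, fh, sort_keys=False)


def load_presets(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_presets() -> dict:
    """The calibrated preset shipped with the package."""
    ref = importlib.resources.files("lipogate") / "presets" / "default_gates.yaml"
    return yaml.safe_load(ref.read_text())
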