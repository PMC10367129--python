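"""End-to-end parameter-recovery experiments on synthetic populations.

Each experiment draws a seed-fixed mixture of phenotype classes at the
default signal-to-noise, pushes it through feature extraction and the
relevant gating cascade, and scores per-class recall/precision and the
deviation of each recovered class fraction from the generator weight in
binomial standard errors. These runs are how the pipeline's class
separability is certified without instrument data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .features import build_feature_table
from .phenotypes import (
    classify_expression,
    classify_filaments,
    classify_morphology,
    classify_ps,
    classify_relocalization,
    classify_replication,
    identify_liposomes,
)
from .synthetic import DEFAULT_OPTICS, PopulationComposition, sample_population

__all__ = [
    "MORPHOLOGY_MIX",
    "MODULE_MIXES",
    "recovery_metrics",
    "run_morphology_recovery",
    "run_module_recovery",
    "run_ps_recovery",
]

#: Mixture used for the identification + morphometry recovery run. Junk
#: classes (aggregate, debris, defocused) are over-represented relative to
#: a clean preparation so that every rejection branch is exercised with
#: enough events for stable per-class metrics.
MORPHOLOGY_MIX = {
    "sphere": 0.20,
    "multilamellar": 0.14,
    "rod": 0.08,
    "doublet": 0.18,
    "aggregate": 0.12,
    "debris": 0.16,
    "out_of_focus": 0.12,
}

#: Truth class -> expected cascade label for the morphology experiment.
MORPHOLOGY_MAP = {
    "sphere": "spherical_unilamellar",
    "multilamellar": "spherical_multilamellar",
    "rod": "rod",
    "doublet": "doublet",
    "aggregate": "aggregate",
    "debris": "debris",
    "out_of_focus": "out_of_focus",
}

MODULE_MIXES = {
    "expression": {
        "mix": {"expressing": 0.6, "nonexpressing": 0.4},
        "column": "expression",
        "map": {"expressing": "expressing", "nonexpressing": "nonexpressing"},
    },
    "replication": {
        "mix": {"repl_negative": 0.40, "repl_homogeneous": 0.35,
                "repl_blob": 0.25},
        "column": "replication",
        "map": {"repl_negative": "negative",
                "repl_homogeneous": "homogeneous",
                "repl_blob": "blob"},
    },
    "filaments": {
        "mix": {"filament_negative": 0.20, "no_filament": 0.55,
                "filament": 0.25},
        "column": "filament",
        "map": {"filament_negative": "below_intensity",
                "no_filament": "no_filament",
                "filament": "filament"},
    },
    "relocalization": {
        "mix": {"min_inactive": 0.5, "min_active": 0.5},
        "column": "relocalization",
        "map": {"min_inactive": "inactive", "min_active": "active"},
    },
}

_CLASSIFIERS = {
    "expression": classify_expression,
    "replication": classify_replication,
    "filaments": classify_filaments,
    "relocalization": classify_relocalization,
}


def recovery_metrics(
    pred: pd.Series, truth: pd.Series, class_map: dict, weights: dict
) -> dict:
    """Per-class recall, precision and fraction recovery.

    ``class_map`` sends each generator class to the cascade label it
    should receive; the recovered fraction of each class is compared with
    the generator weight in binomial standard errors.
    """
    n = len(truth)
    classes = {}
    for cls, expected in class_map.items():
        true_mask = (truth == cls).to_numpy()
        pred_mask = (pred == expected).to_numpy()
        n_true = int(true_mask.sum())
        n_pred = int(pred_mask.sum())
        tp = int((true_mask & pred_mask).sum())
        w = float(weights[cls])
        se = math.sqrt(w * (1 - w) / n)
        frac = n_pred / n
        classes[cls] = {
            "expected_label": expected,
            "weight": w,
            "n_true": n_true,
            "n_pred": n_pred,
            "recall": tp / n_true if n_true else float("nan"),
            "precision": tp / n_pred if n_pred else float("nan"),
            "fraction": frac,
            "deviation_se": abs(frac - w) / se if se > 0 else float("nan"),
        }
    return {
        "n": n,
        "classes": classes,
        "min_recall": min(c["recall"] for c in classes.values()),
        "min_precision": min(c["precision"] for c in classes.values()),
        "max_deviation_se": max(c["deviation_se"] for c in classes.values()),
    }


def run_morphology_recovery(
    n: int = 5000, seed: int = 0, presets: dict | None = None,
    optics=DEFAULT_OPTICS,
) -> dict:
    """Identification + morphology cascade on the full phenotype mixture."""
    comp = PopulationComposition(class_weights=MORPHOLOGY_MIX, n_events=n,
                                 seed=seed)
    events, truth = sample_population(comp, optics)
    table = build_feature_table(events)
    labels, _ = identify_liposomes(table, presets)
    labels = classify_morphology(table, labels, presets)
    pred = labels["morphology"].where(
        labels["identification"] == "good_liposome", labels["identification"]
    )
    return recovery_metrics(pred, truth["class_label"], MORPHOLOGY_MAP,
                            MORPHOLOGY_MIX)


def run_module_recovery(
    module: str, n: int = 2000, seed: int = 0, presets: dict | None = None,
    optics=DEFAULT_OPTICS,
) -> dict:
    """One reporter-module cascade (expression/replication/filaments/
    relocalization) on its 2,000-event default mixture."""
    spec = MODULE_MIXES[module]
    comp = PopulationComposition(class_weights=spec["mix"], n_events=n,
                                 seed=seed)
    events, truth = sample_population(comp, optics)
    table = build_feature_table(events)
    labels, _ = identify_liposomes(table, presets)
    labels = _CLASSIFIERS[module](table, labels, presets=presets)
    return recovery_metrics(labels[spec["column"]], truth["class_label"],
                            spec["map"], spec["mix"])


def run_ps_recovery(
    n: int = 2000, n_negative: int = 1000, seed: int = 0,
    max_fpr: float = 0.05, presets: dict | None = None, optics=DEFAULT_OPTICS,
) -> dict:
    """PS-synthesis cascade: negative-control thresholding + recovery.

    Renders a 60/40 positive/negative mixed sample plus a separate
    all-negative control; the threshold is set on the control and the
    held-out control FPR, positive-class recall/precision and fraction
    recovery are reported.
    """
    mix = {"ps_positive": 0.6, "ps_negative": 0.4}
    comp = PopulationComposition(class_weights=mix, n_events=n, seed=seed)
    events, truth = sample_population(comp, optics)
    table = build_feature_table(events)
    labels, _ = identify_liposomes(table, presets)

    neg_comp = PopulationComposition(class_weights={"ps_negative": 1.0},
                                     n_events=n_negative, seed=seed + 1)
    neg_events, _ = sample_population(neg_comp, optics)
    neg_table = build_feature_table(neg_events)

    # held-out negative sample for the achieved-FPR check
    held_comp = PopulationComposition(class_weights={"ps_negative": 1.0},
                                      n_events=n_negative, seed=seed + 2)
    held_events, _ = sample_population(held_comp, optics)
    held_table = build_feature_table(held_events)

    labels, info = classify_ps(table, neg_table, labels, max_fpr=max_fpr)
    held_vals = held_table["intensity_reporter"].to_numpy(dtype=float)
    held_vals = held_vals[np.isfinite(held_vals)]
    info["held_out_fpr"] = float((held_vals > info["threshold"]).mean())

    metrics = recovery_metrics(
        labels["ps"], truth["class_label"],
        {"ps_positive": "ps_positive", "ps_negative": "ps_negative"}, mix)
    metrics["threshold_info"] = info
    return metrics
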