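#!/usr/bin/env python
"""Regenerate the calibrated gate presets shipped with the package.

All scale-dependent cut-offs (focus, homogeneity, circularity, intensity
thresholds, 2D region polygons, size calibration) are derived from
seed-fixed synthetic training populations; see lipogate.calibration.

Usage:
    python scripts/calibrate_presets.py [--seed 20513] [--out <path>]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from lipogate.calibration import DEFAULT_PRESET_SEED, build_presets, save_presets

DEFAULT_OUT = (Path(__file__).resolve().parent.parent
               / "src" / "lipogate" / "presets" / "default_gates.yaml")


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_PRESET_SEED)
    ap.add_argument("--out", type=Path, default=DEFAULT_OUT)
    args = ap.parse_args()
    presets = build_presets(seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    save_presets(presets, args.out)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
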