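"""Readers/writers for event sets, feature tables, labels and reports.

Event sets are stored as one multi-page TIFF per event (one page per
channel, 16-bit unsigned) plus a CSV manifest (event_id, file, channels,
pixel_size) and an optional ground-truth CSV. Feature tables and labels
are CSV with stable headers; per-stage reports are JSON; galleries are
PNG. All writes are atomic (temp-then-rename).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import ImageEvent

__all__ = [
    "EventSetLoadError",
    "write_event_set",
    "read_event_set",
    "iter_event_batches",
    "write_outputs",
    "write_montage",
]

log = logging.getLogger("lipogate")

DEFAULT_BATCH_SIZE = 100_000


class EventSetLoadError(RuntimeError):
    """Raised when a manifest row cannot be materialized into an event."""


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_event_set(
    events, outdir, truth: pd.DataFrame | None = None,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write events as per-event multi-page uint16 TIFFs plus a manifest.

    Channel order inside each TIFF is the (stable) order of the event's
    channel dict and is recorded in the manifest. Returns the manifest
    path.
    """
    outdir = Path(outdir)
    tiles = outdir / "tiles"
    tiles.mkdir(parents=True, exist_ok=True)
    rows = []
    for ev in events:
        names = list(ev.channels)
        stack = np.stack(
            [np.clip(np.round(ev.channels[c]), 0, 65535).astype(np.uint16)
             for c in names]
        )
        fname = f"{ev.event_id}.tif"
        fpath = tiles / fname

        def _w(tmp, stack=stack):
            tifffile.imwrite(tmp, stack, photometric="minisblack")

        _atomic_write(fpath, _w)
        rows.append(
            {
                "event_id": ev.event_id,
                "file": os.path.join("tiles", fname),
                "channels": ";".join(names),
                "pixel_size": ev.pixel_size,
            }
        )
    manifest = pd.DataFrame(rows)
    if manifest["event_id"].duplicated().any():
        raise ValueError("duplicate event_ids in event set")
    mpath = outdir / manifest_name
    _atomic_write(mpath, lambda tmp: manifest.to_csv(tmp, index=False))
    if truth is not None:
        _atomic_write(outdir / "truth.csv", lambda tmp: truth.to_csv(tmp))
    return mpath


def read_event_set(manifest_path):
    """Lazily yield ImageEvents in manifest order.

    Raises
    ------
    EventSetLoadError
        Naming the offending event_id on a missing file, page-count
        mismatch or non-2D page.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    if manifest["event_id"].duplicated().any():
        raise EventSetLoadError("manifest contains duplicate event_ids")
    for row in manifest.itertuples(index=False):
        eid = str(row.event_id)
        fpath = base / row.file
        names = str(row.channels).split(";")
        if not fpath.exists():
            raise EventSetLoadError(f"event {eid!r}: missing tile file {fpath}")
        data = tifffile.imread(fpath)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise EventSetLoadError(f"event {eid!r}: pages are not 2D rasters")
        if data.shape[0] != len(names):
            raise EventSetLoadError(
                f"event {eid!r}: {data.shape[0]} pages but "
                f"{len(names)} declared channels"
            )
        channels = {n: data[i].astype(float) for i, n in enumerate(names)}
        yield ImageEvent(event_id=eid, channels=channels,
                         pixel_size=float(row.pixel_size))


def iter_event_batches(manifest_path, batch_size: int = DEFAULT_BATCH_SIZE):
    """Yield lists of events of at most ``batch_size``, in manifest order."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batch = []
    for ev in read_event_set(manifest_path):
        batch.append(ev)
        if len(batch) == batch_size:
            yield batch
            batch = []
    if batch:
        yield batch


def write_outputs(
    features: pd.DataFrame,
    labels: pd.DataFrame | None,
    report: dict | None,
    outdir,
    *,
    events=None,
    montage_column: str | None = None,
) -> dict[str, Path]:
    """Write the standard output bundle: feature CSV, per-event label CSV,
    JSON report, and (when events are given) a PNG montage gallery with
    example images per class. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    fpath = outdir / "features.csv"
    _atomic_write(fpath, lambda tmp: features.to_csv(tmp))
    written["features"] = fpath
    if labels is not None:
        lpath = outdir / "labels.csv"
        _atomic_write(lpath, lambda tmp: labels.to_csv(tmp))
        written["labels"] = lpath
    if report is not None:
        rpath = outdir / "report.json"
        _atomic_write(
            rpath,
            lambda tmp: Path(tmp).write_text(json.dumps(report, indent=2,
                                                        default=float)),
        )
        written["report"] = rpath
    if events is not None and labels is not None and montage_column:
        mpath = outdir / "montage.png"
        write_montage(events, labels, montage_column, mpath)
        written["montage"] = mpath
    return written


def write_montage(
    events, labels: pd.DataFrame, column: str, path, per_class: int = 6
) -> None:
    """PNG gallery: up to ``per_class`` example membrane tiles per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_id = {ev.event_id: ev for ev in events}
    classes = [c for c in labels[column].unique() if c in set(labels[column])]
    classes = sorted(str(c) for c in classes)
    nrows = max(len(classes), 1)
    fig, axes = plt.subplots(nrows, per_class,
                             figsize=(1.4 * per_class, 1.4 * nrows),
                             squeeze=False)
    for r, cls in enumerate(classes):
        ids = labels.index[labels[column].astype(str) == cls][:per_class]
        for c in range(per_class):
            ax = axes[r][c]
            ax.axis("off")
            if c < len(ids) and ids[c] in by_id:
                ev = by_id[ids[c]]
                ch = "membrane" if "membrane" in ev.channels else next(iter(ev.channels))
                ax.imshow(ev.channels[ch], cmap="gray")
            if c == 0:
                ax.set_title(cls, fontsize=7, loc="left")
    fig.tight_layout()

    def _w(tmp):
        fig.savefig(tmp, dpi=110, format="png")

    _atomic_write(Path(path), _w)
    plt.close(fig)
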