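"""Photo processing: copy, rename by C-label, and thumbnail.

Raw sample photos are exported as JPEGs named by opaque photo record ids.
To make collections browsable, each collection's best photo is copied to
``data/processed/fulcrum/photos/<C-label>.jpg`` (byte-identical to the raw
file) and an aspect-preserving thumbnail is written under a ``thumbnails``
subfolder. A missing or unreadable raw file is recorded per row
(``photo_status = missing_raw``), never fatal.
"""

from __future__ import annotations

import shutil

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .config import ProcessingConfig
from .project_io import ProjectLayout


def _thumbnail(src, dst, max_dim: int) -> None:
    with Image.open(src) as im:
        im = im.convert("RGB")
        im.thumbnail((max_dim, max_dim))
        im.save(dst, format="JPEG")


def proc_photos(
    final: pd.DataFrame,
    layout: ProjectLayout,
    config: ProcessingConfig | None = None,
) -> pd.DataFrame:
    """Copy, rename, and thumbnail each collection's best photo.

    Returns the input table with ``raw_photo_path``, ``processed_photo_path``,
    ``thumbnail_path`` and ``photo_status`` columns added. Re-running is
    idempotent (outputs are overwritten deterministically). When two
    collections share a C-label the second file gets a ``_2`` suffix so
    nothing is silently overwritten.
    """
    config = config or ProcessingConfig()
    out = final.copy()
    raw_paths, proc_paths, thumb_paths, statuses = [], [], [], []

    # one physical copy per distinct (collection, best photo); rows of the
    # same collection (multiple S-labels) share the copy
    name_counts: dict[str, int] = {}
    done: dict[tuple, tuple] = {}

    for _, row in out.iterrows():
        photo_id = row.get("best_photo_id")
        c_label = row.get("c_label")
        if pd.isna(photo_id):
            raw_paths.append(np.nan)
            proc_paths.append(np.nan)
            thumb_paths.append(np.nan)
            statuses.append("missing_raw")
            continue
        key = (row.get("collection_fulcrum_id"), photo_id)
        if key in done:
            rp, pp, tp, st = done[key]
        else:
            rp = layout.raw_photos_dir / f"{photo_id}.jpg"
            stem = str(c_label) if pd.notna(c_label) else str(photo_id)
            n = name_counts.get(stem, 0) + 1
            name_counts[stem] = n
            fname = f"{stem}.jpg" if n == 1 else f"{stem}_{n}.jpg"
            pp = layout.processed_photos_dir / fname
            tp = layout.thumbnails_dir / fname
            if not rp.exists():
                st = "missing_raw"
                pp = tp = None
            else:
                try:
                    _thumbnail(rp, tp, config.thumbnail_max_dim)
                    shutil.copyfile(rp, pp)
                    st = "ok"
                except (UnidentifiedImageError, OSError):
                    st = "missing_raw"
                    pp = tp = None
            done[key] = (rp, pp, tp, st)
        raw_paths.append(str(rp))
        proc_paths.append(str(pp) if pp else np.nan)
        thumb_paths.append(str(tp) if tp else np.nan)
        statuses.append(st)

    out["raw_photo_path"] = raw_paths
    out["processed_photo_path"] = proc_paths
    out["thumbnail_path"] = thumb_paths
    out["photo_status"] = statuses
    return out
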