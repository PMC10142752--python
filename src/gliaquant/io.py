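"""File I/O: multi-page TIFF image sets with channel names in page
metadata, CSV cell tables / truth tables / results, threshold files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import ChannelImage, MultiplexImageSet

ROI_PAGE_NAME = "__ROI__"


def write_image_set(imgset: MultiplexImageSet, path: str | Path) -> None:
    """Write one image set as a multi-page 32-bit float TIFF.

    Each page's ImageDescription is JSON holding the channel name; the
    first page additionally carries the section metadata (case id, group,
    region, um/px). The ROI is stored as a trailing uint8 page named
    __ROI__.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        first = True
        for name, ch in imgset.channels.items():
            meta = {"channel": name}
            if first:
                meta.update(
                    case_id=imgset.case_id,
                    group=imgset.group,
                    region=imgset.region,
                    um_per_px=imgset.um_per_px,
                )
                first = False
            tw.write(ch.pixels.astype(np.float32), description=json.dumps(meta))
        tw.write(
            imgset.roi.astype(np.uint8),
            description=json.dumps({"channel": ROI_PAGE_NAME}),
        )


def read_image_set(path: str | Path) -> MultiplexImageSet:
    """Read an image set written by :func:`write_image_set`."""
    channels: dict[str, ChannelImage] = {}
    roi = None
    meta: dict = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            desc = json.loads(page.description)
            if i == 0:
                meta = {k: v for k, v in desc.items() if k != "channel"}
            name = desc["channel"]
            arr = page.asarray()
            if name == ROI_PAGE_NAME:
                roi = arr.astype(bool)
            else:
                channels[name] = ChannelImage(
                    arr.astype(float), name, float(meta["um_per_px"])
                )
    if roi is None:
        shape = next(iter(channels.values())).shape
        roi = np.ones(shape, dtype=bool)
    return MultiplexImageSet(
        channels=channels,
        roi=roi,
        case_id=str(meta.get("case_id", "")),
        group=str(meta.get("group", "")),
        region=str(meta.get("region", "")),
        um_per_px=float(meta["um_per_px"]),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
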