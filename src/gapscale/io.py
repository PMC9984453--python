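"""File formats: profile/boundary CSV dialects, TIFF images, ground truth.

Profile CSV: one row per embryo x gene x bin with columns
``embryo_id, line, time_class, length_um, gene, bin_index, xi_center,
intensity`` (bin_index 0..49).  Boundary CSV: ``embryo_id, line,
time_class, gene, boundary_name, polarity, xi``.  Images travel as
3-page TIFF stacks in channel order nuclear / FISH / DIC-proxy with the
pixel size and metadata in the TIFF description.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .render import EmbryoImage

PROFILE_COLUMNS = [
    "embryo_id", "line", "time_class", "length_um", "gene",
    "bin_index", "xi_center", "intensity",
]

BOUNDARY_COLUMNS = [
    "embryo_id", "line", "time_class", "gene", "boundary_name",
    "polarity", "xi",
]


def write_profiles(df: pd.DataFrame, path) -> None:
    df[PROFILE_COLUMNS].to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    return df


def write_boundaries(df: pd.DataFrame, path) -> None:
    df[BOUNDARY_COLUMNS].to_csv(path, index=False)


def read_boundaries(path, lengths: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a boundary table; optionally join per-embryo lengths.

    ``lengths`` is any frame with ``embryo_id`` and ``length_um`` (e.g. the
    cohort's embryo metadata, or a profiles table), needed for scaling
    analyses since the boundary dialect itself carries none.
    """
    df = pd.read_csv(path)
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"boundary CSV missing columns: {sorted(missing)}")
    if lengths is not None and "length_um" not in df.columns:
        lut = lengths[["embryo_id", "length_um"]].drop_duplicates("embryo_id")
        df = df.merge(lut, on="embryo_id", how="left")
    return df


def write_embryo_tiff(image: EmbryoImage, path) -> None:
    stack = np.stack(
        [image.nuclear_channel, image.fish_channel, image.dic_proxy_channel]
    ).astype(np.float32)
    desc = json.dumps(
        {"pixel_size_um": image.pixel_size_um, "metadata": image.metadata}
    )
    tifffile.imwrite(path, stack, description=desc)


def read_embryo_tiff(path) -> EmbryoImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    info = json.loads(desc) if desc else {"pixel_size_um": 1.0, "metadata": {}}
    return EmbryoImage(
        nuclear_channel=stack[0].astype(float),
        fish_channel=stack[1].astype(float),
        dic_proxy_channel=stack[2].astype(float),
        pixel_size_um=info["pixel_size_um"],
        metadata=info.get("metadata", {}),
    )
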