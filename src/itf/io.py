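"""File round-trips for the pipeline's plain-text/raster interchange formats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic.fibers import SyntheticFiberImage


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_image(path: Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: Path) -> np.ndarray:
    return iio.imread(Path(path)) > 0


def save_fiber_image(out_dir: Path, im: SyntheticFiberImage, stem: str) -> dict[str, Path]:
    """TIFF image + PNG masks + CSV truth table; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.tif",
        "truth_mask": out_dir / f"{stem}_truth.png",
        "tissue_mask": out_dir / f"{stem}_tissue.png",
        "truth_table": out_dir / f"{stem}_truth.csv",
    }
    write_image(paths["image"], im.image)
    write_mask(paths["truth_mask"], im.truth_mask)
    write_mask(paths["tissue_mask"], im.tissue_mask)
    pd.DataFrame(im.truth_table).to_csv(paths["truth_table"], index=False)
    return paths


def write_matrix_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), sep="\t")


def read_matrix_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def write_json(path: Path, obj) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path: Path):
    with open(Path(path)) as fh:
        return json.load(fh)


def read_roi_geojson(path: Path) -> dict[str, list]:
    """GeoJSON polygons (um coordinates) grouped by a 'category' property."""
    from shapely.geometry import shape

    data = read_json(path)
    out: dict[str, list] = {}
    for feature in data.get("features", []):
        cat = feature.get("properties", {}).get("category", "unknown")
        out.setdefault(cat, []).append(shape(feature["geometry"]))
    return out
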