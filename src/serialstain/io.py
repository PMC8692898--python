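"""Readers and writers for the on-disk exchange formats.

Images: 8-bit RGB TIFF/PNG (tifffile / Pillow). Annotations: GeoJSON
FeatureCollection, one polygon feature per compartment with a ``label``
property. Deformation fields: NPZ holding the (H, W, 2) displacement array,
with a JSON sidecar recording scale and convention. Landmarks: CSV with
columns row_fixed, col_fixed, row_moving, col_moving. Expression: MatrixMarket
plus gene/cell TSVs, or a single dense CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from PIL import Image as _PILImage
from scipy import io as spio
from scipy import sparse
from shapely.geometry import mapping as _geom_mapping, shape as _geom_shape
import tifffile

from .types import DeformationField, RegionAnnotation, SlideImage


# --- images ---------------------------------------------------------------


def save_image(image: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        _PILImage.fromarray(image.pixels).save(path)


def load_image(path, marker: str = "", section_index: int = 0) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(_PILImage.open(path).convert("RGB"))
    return SlideImage(arr, marker=marker, section_index=section_index)


# --- annotations ----------------------------------------------------------


def save_annotation(annotation: RegionAnnotation, path) -> None:
    """Write compartments as a GeoJSON FeatureCollection (property "label")."""
    features = [
        {"type": "Feature", "properties": {"label": label}, "geometry": _geom_mapping(geom)}
        for label, geom in annotation.compartments.items()
    ]
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"height": int(annotation.shape[0]), "width": int(annotation.shape[1])},
    }
    Path(path).write_text(json.dumps(doc))


def load_annotation(path, tissue_mask: np.ndarray | None = None) -> RegionAnnotation:
    """Read a GeoJSON FeatureCollection written by :func:`save_annotation`.

    When no tissue mask is supplied, the union of all compartments is
    rasterized as the tissue.
    """
    from .geometry import rasterize_geometry
    from shapely.ops import unary_union

    doc = json.loads(Path(path).read_text())
    compartments = {
        f["properties"]["label"]: _geom_shape(f["geometry"]) for f in doc["features"]
    }
    if tissue_mask is None:
        props = doc.get("properties", {})
        shape = (props["height"], props["width"])
        tissue_mask = rasterize_geometry(unary_union(list(compartments.values())), shape)
    return RegionAnnotation(compartments=compartments, tissue_mask=tissue_mask)


# --- deformation fields ---------------------------------------------------


def save_field(field: DeformationField, path) -> None:
    """NPZ with the displacement array plus a JSON sidecar stating conventions."""
    path = Path(path)
    np.savez_compressed(path, disp=field.disp, scale=np.float64(field.scale))
    sidecar = {
        "scale": field.scale,
        "convention": "pull-back; disp[r, c] = (d_row, d_col) px; 0-based",
        "shape": list(field.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_field(path) -> DeformationField:
    with np.load(Path(path)) as z:
        return DeformationField(z["disp"], scale=float(z["scale"]))


# --- landmarks ------------------------------------------------------------

_LANDMARK_COLS = ["row_fixed", "col_fixed", "row_moving", "col_moving"]


def save_landmarks(pairs: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(pairs, float), columns=_LANDMARK_COLS).to_csv(path, index=False)


def load_landmarks(path) -> np.ndarray:
    return pd.read_csv(path)[_LANDMARK_COLS].to_numpy(dtype=float)


# --- expression -----------------------------------------------------------


def save_expression(adata: ad.AnnData, out_dir) -> None:
    """Write MatrixMarket matrix.mtx plus genes.tsv / cells.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    spio.mmwrite(out_dir / "matrix.mtx", sparse.csr_matrix(np.asarray(X)))
    pd.Series(adata.var_names).to_csv(out_dir / "genes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(out_dir / "cells.tsv", sep="\t")


def load_expression(in_dir) -> ad.AnnData:
    in_dir = Path(in_dir)
    X = np.asarray(spio.mmread(in_dir / "matrix.mtx").todense(), dtype=np.float64)
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(in_dir / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def load_signature(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes
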