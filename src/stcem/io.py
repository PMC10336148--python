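"""Readers and writers for the pipeline's on-disk formats.

Cell tables and landmark pairs travel as TSV, count matrices as an MTX
triplet (matrix.mtx + genes.tsv + cells.tsv), gene-set collections as
GMT, region polygons as GeoJSON, transform chains and ground-truth
records as JSON. All writers are deterministic (fixed float format,
fixed ordering) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import mapping, shape

from .lesion import RegionSet
from .registration import LandmarkSet
from .types import CountsMatrix

FLOAT_FMT = "%.10g"


# -- cell tables -------------------------------------------------------

def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- counts (MTX triplet) ---------------------------------------------

def write_counts_mtx(counts: CountsMatrix, outdir) -> None:
    """matrix.mtx (genes × cells, raw) + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(counts.raw).T)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.DataFrame(
        {"gene": counts.gene_names, "is_blank": counts.is_blank.astype(int)}
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": counts.cell_ids}).to_csv(
        outdir / "cells.tsv", sep="\t", index=False
    )


def read_counts_mtx(outdir) -> CountsMatrix:
    outdir = Path(outdir)
    mat = spio.mmread(outdir / "matrix.mtx").toarray().T
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")
    return CountsMatrix(
        cell_ids=cells["cell_id"].to_numpy(object),
        gene_names=genes["gene"].to_numpy(object),
        raw=mat,
        is_blank=genes["is_blank"].to_numpy(bool)
        if "is_blank" in genes
        else None,
    )


# -- landmarks ---------------------------------------------------------

def write_landmarks(lm: LandmarkSet, path) -> None:
    pd.DataFrame(
        {
            "x_src": lm.source[:, 0],
            "y_src": lm.source[:, 1],
            "x_dst": lm.target[:, 0],
            "y_dst": lm.target[:, 1],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path, sep="\t")
    return LandmarkSet(
        source=df[["x_src", "y_src"]].to_numpy(float),
        target=df[["x_dst", "y_dst"]].to_numpy(float),
    )


# -- gene sets (GMT) ---------------------------------------------------

def read_gmt(path) -> Dict[str, list]:
    """GMT: one set per line, tab-separated: name, description, genes..."""
    out: Dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gmt(sets: Dict[str, list], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- regions (GeoJSON) -------------------------------------------------

def write_regions(regions: RegionSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(poly),
        }
        for name, poly in regions.polygons.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_regions(path) -> RegionSet:
    data = json.loads(Path(path).read_text())
    polys = {
        f["properties"]["name"]: shape(f["geometry"]) for f in data["features"]
    }
    return RegionSet(polygons=polys)


# -- misc --------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
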