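"""Plain-text readers and writers for the pipeline's file formats.

All formats are delimited text: an N x N connectivity matrix (whitespace or
comma separated), a tab-separated atlas (index, name, hemisphere, lobe,
homotopic_index; 0-based indices), a tab-separated volumetrics table
(subject_id, group, focus_side, then one column per region in atlas order),
and small JSON sidecars for planted truth and run manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atrophy import VolumetricsTable
from .graph_core import Connectome, GraphError, RegionAtlas
from .synthetic_data import PlantedTruth

ATLAS_COLUMNS = ("index", "name", "hemisphere", "lobe", "homotopic_index")


def write_matrix(path: str | Path, C: np.ndarray) -> None:
    np.savetxt(path, np.asarray(C, dtype=float), fmt="%.12g", delimiter=" ")


def read_matrix(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def write_atlas(path: str | Path, atlas: RegionAtlas) -> None:
    df = pd.DataFrame(
        {
            "index": range(atlas.n_regions),
            "name": atlas.names,
            "hemisphere": atlas.hemispheres,
            "lobe": atlas.lobes,
            "homotopic_index": atlas.homotopic,
        }
    )
    with open(path, "w") as fh:
        fh.write("# region atlas; indices are 0-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_atlas(path: str | Path) -> RegionAtlas:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ATLAS_COLUMNS) - set(df.columns)
    if missing:
        raise GraphError(f"atlas file missing columns: {sorted(missing)}")
    df = df.sort_values("index")
    if list(df["index"]) != list(range(len(df))):
        raise GraphError("atlas indices must be 0..N-1 without gaps")
    return RegionAtlas(
        tuple(df["name"].astype(str)),
        tuple(df["hemisphere"].astype(str)),
        tuple(df["lobe"].astype(str)),
        tuple(int(i) for i in df["homotopic_index"]),
    )


def read_connectome(matrix_path: str | Path, atlas_path: str | Path) -> Connectome:
    return Connectome(atlas=read_atlas(atlas_path), C=read_matrix(matrix_path))


def write_volumetrics(
    path: str | Path, table: VolumetricsTable, atlas: RegionAtlas
) -> None:
    df = pd.DataFrame(table.volumes, columns=list(atlas.names))
    df.insert(0, "focus_side", table.focus_sides)
    df.insert(0, "group", table.groups)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_volumetrics(path: str | Path, atlas: RegionAtlas) -> VolumetricsTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("subject_id", "group", "focus_side"):
        if col not in df.columns:
            raise GraphError(f"volumetrics file missing column {col!r}")
    region_cols = [c for c in df.columns if c not in ("subject_id", "group", "focus_side")]
    if tuple(region_cols) != atlas.names:
        raise GraphError("volumetrics region columns do not match the atlas order")
    return VolumetricsTable(
        tuple(df["subject_id"].astype(str)),
        tuple(df["group"].astype(str)),
        tuple(df["focus_side"].astype(str)),
        df[region_cols].to_numpy(dtype=float),
    )


def write_truth(path: str | Path, truth: PlantedTruth) -> None:
    payload = {
        "model": truth.model,
        "seed_regions": list(truth.seed_regions),
        "t": truth.t,
        "kappa": truth.kappa,
        "pattern": [float(v) for v in truth.pattern],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        model=payload["model"],
        seed_regions=tuple(payload["seed_regions"]),
        t=float(payload["t"]),
        kappa=float(payload["kappa"]),
        pattern=np.asarray(payload["pattern"], dtype=float),
    )


def write_estimate(
    path: str | Path, values: np.ndarray, atlas: RegionAtlas
) -> None:
    """Two-column region/value export, atlas order."""
    pd.DataFrame({"region": atlas.names, "value": np.asarray(values, float)}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
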