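"""Plain-text readers and writers for the package's file dialects.

Connectivity matrices travel as tab-separated R x R numeric grids with an
ROI-id header row and column; per-ROI maps as two-column ``roi_id\tvalue``
tables; streamlines either as MRtrix TCK (via nibabel) or as a small JSON
dialect (list of point-lists) convenient for fixtures. Numeric text output
uses 12 significant digits so that re-runs are byte-comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .parcellation import Parcellation
from .synthetic import StreamlineSet

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_map",
    "read_map",
    "write_streamlines_json",
    "read_streamlines_json",
    "write_streamlines_tck",
    "read_streamlines_tck",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.12g"


def write_matrix(values: np.ndarray, parc: Parcellation, path) -> None:
    """Write an R x R matrix as TSV with ROI ids on both axes."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=parc.roi_ids, columns=parc.roi_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="roi_id")


def read_matrix(path, parc: Parcellation = None) -> np.ndarray:
    """Read a TSV matrix; when a parcellation is given, verify ROI order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if parc is not None:
        if list(df.index.astype(str)) != list(parc.roi_ids) or list(
            df.columns.astype(str)
        ) != list(parc.roi_ids):
            raise ValueError(f"ROI ordering in {path} does not match the parcellation")
    return df.to_numpy(dtype=float)


def write_map(values: np.ndarray, parc: Parcellation, path) -> None:
    """Write a per-ROI scalar map as ``roi_id\tvalue``."""
    pd.DataFrame({"roi_id": parc.roi_ids, "value": np.asarray(values, dtype=float)}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_map(path, parc: Parcellation = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
    if parc is not None and list(df["roi_id"]) != list(parc.roi_ids):
        raise ValueError(f"ROI ordering in {path} does not match the parcellation")
    return df["value"].to_numpy(dtype=float)


def write_streamlines_json(streams: StreamlineSet, path) -> None:
    payload = {
        "streamlines": [np.asarray(s, dtype=float).tolist() for s in streams.streamlines],
        "endpoint_rois": [list(p) for p in streams.endpoint_rois],
    }
    Path(path).write_text(json.dumps(payload))


def read_streamlines_json(path) -> StreamlineSet:
    payload = json.loads(Path(path).read_text())
    return StreamlineSet(
        streamlines=[np.asarray(s, dtype=float) for s in payload["streamlines"]],
        endpoint_rois=[tuple(p) for p in payload["endpoint_rois"]],
    )


def write_streamlines_tck(streams: StreamlineSet, path) -> None:
    """Write streamlines (mm coordinates) as an MRtrix TCK track file."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    tractogram = Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streams.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


def read_streamlines_tck(path, endpoint_rois=None) -> StreamlineSet:
    """Read a TCK file; endpoint ROI labels must be supplied separately."""
    import nibabel as nib

    tck = nib.streamlines.load(str(path))
    streams = [np.asarray(s, dtype=float) for s in tck.streamlines]
    if endpoint_rois is None:
        endpoint_rois = [("", "")] * len(streams)
    return StreamlineSet(streamlines=streams, endpoint_rois=list(endpoint_rois))


def write_cohort(cohort, parc: Parcellation, outdir, modality: str, seed=None) -> Path:
    """Write one matrix file per subject (and session) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, item in enumerate(cohort):
        sid = f"sub{i:03d}"
        sessions = item if isinstance(item, (list, tuple)) else [item]
        for s, mat in enumerate(sessions):
            v = mat.values if isinstance(mat, ConnectivityMatrix) else mat
            name = f"{sid}_ses{s + 1}_{modality}.tsv" if len(sessions) > 1 else f"{sid}_{modality}.tsv"
            write_matrix(v, parc, outdir / name)
            entries.append({"subject": sid, "session": s + 1, "file": name})
    manifest = {
        "modality": modality,
        "n_subjects": len(cohort),
        "seed": seed,
        "files": entries,
    }
    mpath = outdir / f"{modality}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_manifest(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
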