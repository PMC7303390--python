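"""Readers and writers for the pipeline's on-disk formats.

CSV is the canonical matrix format (labeled, full double precision,
diff-able); label volumes go to NIfTI; streamlines go to TRK (via
nibabel) or to a plain-text TSV dialect with one point per line:
``streamline_id  x  y  z  qa``.  Every writer's output is re-readable
by the matching reader (closure property).
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .connectomes import ConnMatrix, GroupingScheme, StreamlineSet

__all__ = [
    "read_conn_csv", "write_conn_csv",
    "read_streamlines_tsv", "write_streamlines_tsv",
    "read_streamlines_trk", "write_streamlines_trk",
    "read_streamlines",
    "read_grouping_csv", "write_grouping_csv",
    "read_traits_csv", "write_traits_csv",
    "read_label_volume", "write_label_volume",
    "read_config_toml",
]

# %.17g prints doubles losslessly, so CSV round-trips are bit-identical
FLOAT_FMT = "%.17g"


def write_conn_csv(m: ConnMatrix, path: str | Path) -> None:
    """Labeled CSV: first row/column are parcel labels."""
    df = pd.DataFrame(m.weights, index=m.parcel_labels, columns=m.parcel_labels)
    df.index.name = m.weight_kind
    df.to_csv(path, float_format=FLOAT_FMT)


def read_conn_csv(path: str | Path, weight_kind: str | None = None) -> ConnMatrix:
    """Read a labeled connectivity CSV, validating symmetry and labels."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    if len(set(rows)) != len(rows):
        raise ValueError(f"{path}: duplicated parcel labels")
    w = df.to_numpy(dtype=float)
    if np.max(np.abs(w - w.T), initial=0.0) > 1e-9:
        raise ValueError(f"{path}: matrix asymmetric beyond 1e-9")
    kind = weight_kind or (df.index.name if df.index.name in
                           ("FCz", "NS", "ML", "QA") else "FCz")
    return ConnMatrix(w, rows, kind)


def write_streamlines_tsv(streams: StreamlineSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("streamline_id\tx\ty\tz\tqa\n")
        for sid, poly in enumerate(streams.polylines):
            qa = streams.qa[sid] if streams.qa is not None else np.full(len(poly), np.nan)
            for (x, y, z), q in zip(poly, qa):
                fh.write(f"{sid}\t{x:.9g}\t{y:.9g}\t{z:.9g}\t{q:.9g}\n")


def read_streamlines_tsv(path: str | Path) -> StreamlineSet:
    """Read the plain-text polyline dialect, enforcing >= 2 points each."""
    df = pd.read_csv(path, sep="\t")
    expected = ["streamline_id", "x", "y", "z", "qa"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    polys, qa = [], []
    have_qa = not df["qa"].isna().all()
    for sid, grp in df.groupby("streamline_id", sort=True):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if pts.shape[0] < 2:
            raise ValueError(f"{path}: streamline {sid} has fewer than 2 points")
        polys.append(pts)
        qa.append(grp["qa"].to_numpy(dtype=float))
    return StreamlineSet(polys, qa if have_qa else None)


def write_streamlines_trk(streams: StreamlineSet, path: str | Path,
                          voxel_size: float = 2.0) -> None:
    """TRK export through nibabel, QA as a per-point data channel."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    affine = np.diag([voxel_size] * 3 + [1.0])
    data_per_point = None
    if streams.qa is not None:
        data_per_point = {"qa": [q.reshape(-1, 1) for q in streams.qa]}
    tg = Tractogram(streams.polylines, data_per_point=data_per_point,
                    affine_to_rasmm=np.eye(4))
    hdr = TrkFile.create_empty_header()
    hdr["voxel_sizes"] = [voxel_size] * 3
    hdr["voxel_to_rasmm"] = affine
    hdr["voxel_order"] = "RAS"
    TrkFile(tg, header=hdr).save(str(path))


def read_streamlines_trk(path: str | Path) -> StreamlineSet:
    from nibabel.streamlines import load as nib_load

    trk = nib_load(str(path))
    tg = trk.tractogram
    polys = [np.asarray(s, dtype=float) for s in tg.streamlines]
    for i, p in enumerate(polys):
        if p.shape[0] < 2:
            raise ValueError(f"{path}: streamline {i} has fewer than 2 points")
    qa = None
    if "qa" in tg.data_per_point:
        qa = [np.asarray(q, dtype=float).ravel() for q in tg.data_per_point["qa"]]
    return StreamlineSet(polys, qa)


def read_streamlines(path: str | Path) -> StreamlineSet:
    """Dispatch on extension: .trk binary or .tsv text dialect."""
    path = Path(path)
    if path.suffix == ".trk":
        return read_streamlines_trk(path)
    if path.suffix in (".tsv", ".txt"):
        return read_streamlines_tsv(path)
    raise ValueError(f"{path}: unknown streamline format (expect .trk or .tsv)")


def write_grouping_csv(g: GroupingScheme, path: str | Path) -> None:
    pd.DataFrame(
        {"parcel": list(g.parcel_to_group), "group": list(g.parcel_to_group.values())}
    ).to_csv(path, index=False)


def read_grouping_csv(path: str | Path, name: str | None = None) -> GroupingScheme:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["parcel", "group"]:
        raise ValueError(f"{path}: expected columns parcel,group")
    if df["parcel"].duplicated().any():
        dup = df.loc[df["parcel"].duplicated(), "parcel"].iloc[0]
        raise ValueError(f"{path}: parcel {dup!r} mapped more than once")
    return GroupingScheme(name or Path(path).stem,
                          dict(zip(df["parcel"], df["group"])))


def write_traits_csv(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, float_format=FLOAT_FMT)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_label_volume(labels: np.ndarray, path: str | Path,
                       voxel_size: float = 2.0) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32),
                          np.diag([voxel_size] * 3 + [1.0]))
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=np.int32), voxel_size


def read_config_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
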