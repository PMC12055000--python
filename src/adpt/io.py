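"""Dataset and track input/output.

Two labeled-dataset layouts are supported:

* the native layout — ``images/`` directory, one long-format
  ``annotations.csv`` (image, identity, bodypart, x, y, visible) and a
  ``skeleton.yaml``;
* DeepLabCut-style multi-index tables (CSV or HDF5) with
  scorer / [individuals /] bodyparts / coords header rows, which a
  converter ingests into the native layout.

Absent or NaN table cells mean "not annotated" (visibility 0), never (0, 0).
Decoded tracks are written back out in the DeepLabCut-style
x / y / likelihood layout so downstream kinematic tooling can read them.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd

from .config import Config
from .frames import Instance, LabeledFrame, PoseTrack
from .skeleton import Skeleton

__all__ = [
    "read_labeled_dataset",
    "write_labeled_dataset",
    "read_dlc_table",
    "convert_dlc_dataset",
    "write_track",
    "read_track",
]


# ---------------------------------------------------------------------------
# native layout
# ---------------------------------------------------------------------------

def write_labeled_dataset(path, frames, skeleton: Skeleton) -> None:
    """Write frames in the native layout (images/ + annotations.csv + YAML)."""
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, frame in enumerate(frames):
        name = frame.name or f"img{idx:05d}.png"
        name = name.replace("/", "_").replace("\\", "_")
        if not name.lower().endswith((".png", ".jpg", ".jpeg")):
            name += ".png"
        img = frame.image
        if img.dtype != np.uint8:
            img = np.clip(img, 0, 255).astype(np.uint8)
        imageio.imwrite(root / "images" / name, img.squeeze())
        for inst in frame.instances:
            for k, bodypart in enumerate(skeleton.names):
                x, y = inst.keypoints[k]
                rows.append(
                    {
                        "image": name,
                        "identity": inst.identity,
                        "bodypart": bodypart,
                        "x": x,
                        "y": y,
                        "visible": int(inst.visibility[k]),
                    }
                )
    pd.DataFrame(rows).to_csv(root / "annotations.csv", index=False)
    skeleton.save(root / "skeleton.yaml")


def read_labeled_dataset(path, config: Config, skeleton: Skeleton | None = None):
    """Read a labeled dataset (native layout, or a DLC-style table).

    Returns a list of LabeledFrame with keypoints in original pixel
    coordinates. A table row whose image file is missing is a hard error
    naming the row; a bodypart set differing from the skeleton is a hard
    error.
    """
    root = Path(path)
    if (root / "annotations.csv").exists():
        return _read_native(root, skeleton)
    # fall back to a DLC-style table anywhere under the directory
    candidates = sorted(root.glob("*.h5")) + sorted(root.glob("*.csv"))
    if not candidates:
        raise FileNotFoundError(f"no annotations.csv or DLC-style table in {root}")
    return read_dlc_table(candidates[0], root, skeleton)


def _read_native(root: Path, skeleton: Skeleton | None):
    if skeleton is None:
        skeleton = Skeleton.load(root / "skeleton.yaml")
    table = pd.read_csv(root / "annotations.csv")
    parts = set(table["bodypart"].unique())
    if parts != set(skeleton.names):
        raise ValueError(
            f"bodypart set {sorted(parts)} does not match skeleton {list(skeleton.names)}"
        )
    frames = []
    for name, group in table.groupby("image", sort=True):
        img_path = root / "images" / name
        if not img_path.exists():
            raise FileNotFoundError(
                f"annotation row references missing image file: {name}"
            )
        image = imageio.imread(img_path)
        instances = []
        for identity, sub in group.groupby("identity", sort=True):
            kp = np.full((skeleton.n_keypoints, 2), np.nan)
            vis = np.zeros(skeleton.n_keypoints, dtype=bool)
            for _, row in sub.iterrows():
                k = skeleton.index(row["bodypart"])
                kp[k] = (row["x"], row["y"])
                vis[k] = bool(row["visible"]) and np.isfinite(row["x"]) and np.isfinite(row["y"])
            instances.append(Instance(int(identity), kp, vis))
        frames.append(LabeledFrame(image, instances, name=str(name)))
    return frames


# ---------------------------------------------------------------------------
# DeepLabCut-style tables
# ---------------------------------------------------------------------------

def _load_dlc_frame_table(table_path: Path) -> pd.DataFrame:
    table_path = Path(table_path)
    if table_path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(table_path)
    else:
        with open(table_path) as fh:
            head = [fh.readline().split(",")[0].strip() for _ in range(4)]
        n_header = 4 if "individuals" in head else 3
        df = pd.read_csv(table_path, header=list(range(n_header)), index_col=0)
    return df


def read_dlc_table(table_path, images_root, skeleton: Skeleton | None = None):
    """Read a DLC-style annotation table into LabeledFrames.

    The table's multi-index columns are scorer / [individuals /]
    bodyparts / coords; the row index holds image paths relative to
    ``images_root``. NaN cells become visibility 0.
    """
    images_root = Path(images_root)
    df = _load_dlc_frame_table(table_path)
    has_individuals = "individuals" in (df.columns.names or [])
    bp_level = "bodyparts" if "bodyparts" in (df.columns.names or []) else -2
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(bp_level)))
    if skeleton is None:
        skeleton = Skeleton(tuple(bodyparts), (), 0)
    elif set(bodyparts) != set(skeleton.names):
        raise ValueError(
            f"bodypart set {sorted(bodyparts)} does not match skeleton "
            f"{list(skeleton.names)}"
        )
    frames = []
    for row_name, row in df.iterrows():
        rel = row_name if isinstance(row_name, str) else os.path.join(*row_name)
        img_path = images_root / rel
        if not img_path.exists():
            raise FileNotFoundError(
                f"annotation row references missing image file: {rel}"
            )
        image = imageio.imread(img_path)
        instances = []
        if has_individuals:
            individuals = list(
                dict.fromkeys(df.columns.get_level_values("individuals"))
            )
            groups = [
                (i + 1, row.xs(ind, level="individuals"))
                for i, ind in enumerate(individuals)
            ]
        else:
            groups = [(1, row.droplevel(0))]
        for identity, sub in groups:
            kp = np.full((skeleton.n_keypoints, 2), np.nan)
            vis = np.zeros(skeleton.n_keypoints, dtype=bool)
            for name in skeleton.names:
                k = skeleton.index(name)
                try:
                    x = float(sub[(name, "x")])
                    y = float(sub[(name, "y")])
                except KeyError:
                    continue
                kp[k] = (x, y)
                vis[k] = np.isfinite(x) and np.isfinite(y)
            if np.any(vis):
                instances.append(Instance(int(identity), kp, vis))
        frames.append(LabeledFrame(image, instances, name=str(rel)))
    return frames


def convert_dlc_dataset(table_path, images_root, out_dir, skeleton: Skeleton) -> int:
    """Convert a DLC-style labeled dataset to the native layout.

    Returns the number of frames converted.
    """
    frames = read_dlc_table(table_path, images_root, skeleton)
    write_labeled_dataset(out_dir, frames, skeleton)
    return len(frames)


# ---------------------------------------------------------------------------
# decoded tracks
# ---------------------------------------------------------------------------

def write_track(path, track: PoseTrack, skeleton: Skeleton, scorer: str = "adpt"):
    """Write a PoseTrack as a DLC-style x/y/likelihood table (CSV or HDF5)."""
    path = Path(path)
    F, I, K, _ = track.keypoints.shape
    multi = I > 1
    cols, data = [], []
    for s in range(I):
        ind = f"individual{s + 1}"
        for k, bp in enumerate(skeleton.names):
            for coord in ("x", "y", "likelihood"):
                cols.append((scorer, ind, bp, coord) if multi else (scorer, bp, coord))
        for k in range(K):
            data.append(track.keypoints[:, s, k, 0])
            data.append(track.keypoints[:, s, k, 1])
            data.append(track.confidences[:, s, k])
    names = (
        ["scorer", "individuals", "bodyparts", "coords"]
        if multi
        else ["scorer", "bodyparts", "coords"]
    )
    df = pd.DataFrame(
        np.column_stack(data), columns=pd.MultiIndex.from_tuples(cols, names=names)
    )
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="tracks", mode="w")
    else:
        df.to_csv(path)
    return df


def read_track(path, skeleton: Skeleton) -> PoseTrack:
    """Read a DLC-style x/y/likelihood table back into a PoseTrack."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path)
    else:
        with open(path) as fh:
            head = [fh.readline().split(",")[0].strip() for _ in range(4)]
        n_header = 4 if "individuals" in head else 3
        df = pd.read_csv(path, header=list(range(n_header)), index_col=0)
    multi = "individuals" in (df.columns.names or [])
    F = len(df)
    K = skeleton.n_keypoints
    if multi:
        individuals = list(dict.fromkeys(df.columns.get_level_values("individuals")))
    else:
        individuals = [None]
    I = len(individuals)
    kp = np.full((F, I, K, 2), np.nan)
    conf = np.zeros((F, I, K))
    ids = np.zeros((F, I), dtype=np.int64)
    for s, ind in enumerate(individuals):
        sub = df.xs(ind, axis=1, level="individuals") if multi else df
        sub = sub.droplevel(0, axis=1)
        for k, bp in enumerate(skeleton.names):
            kp[:, s, k, 0] = sub[(bp, "x")].to_numpy()
            kp[:, s, k, 1] = sub[(bp, "y")].to_numpy()
            conf[:, s, k] = np.nan_to_num(sub[(bp, "likelihood")].to_numpy())
        ids[:, s] = s + 1
    centers = kp[:, :, 0, :].copy()
    return PoseTrack(kp, np.clip(conf, 0, 1), ids, centers)
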