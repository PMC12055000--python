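"""Skeleton definition: named keypoints, directed limb edges, body center.

The skeleton drives three things downstream: which limb segments the
low-resolution semantic segmentation (LRSS) paints, which keypoint anchors
the body affinity field (BAF) vectors, and how the PCK reference length
``L_i`` is derived for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = ["Skeleton", "MOUSE5"]


@dataclass(frozen=True)
class Skeleton:
    """Named keypoints plus directed limb edges and a designated center.

    Parameters
    ----------
    names
        Ordered keypoint labels; index order fixes channel order everywhere.
    edges
        Directed limb edges as ``(i, j)`` keypoint-index pairs.
    center_index
        Index of the keypoint used as the body center (BAF anchor); for
        rodents this is conventionally the back.
    pck_reference
        Rule for the per-instance normalization length ``L_i`` used by PCK:
        ``"bbox_sqrt"`` (square root of the ground-truth bounding-box area,
        the default) or an edge label ``"edge:<i>-<j>"`` meaning the length
        of that limb.
    """

    names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    center_index: int
    pck_reference: str = "bbox_sqrt"

    def __post_init__(self) -> None:
        k = len(self.names)
        if k == 0:
            raise ValueError("skeleton needs at least one keypoint")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        for i, j in self.edges:
            if not (0 <= i < k and 0 <= j < k):
                raise ValueError(f"edge ({i}, {j}) has out-of-range keypoint index")
            if i == j:
                raise ValueError(f"self-edge ({i}, {j}) not allowed")
        if not 0 <= self.center_index < k:
            raise ValueError(f"center_index {self.center_index} out of range")

    @property
    def n_keypoints(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "edges": [list(e) for e in self.edges],
            "center": self.names[self.center_index],
            "pck_reference": self.pck_reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        names = list(d["names"])
        center = d.get("center", names[0])
        center_index = names.index(center) if isinstance(center, str) else int(center)
        return cls(
            names=tuple(names),
            edges=tuple(tuple(e) for e in d.get("edges", [])),
            center_index=center_index,
            pck_reference=d.get("pck_reference", "bbox_sqrt"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Skeleton":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Default 5-keypoint rodent-like body: nose, back (center), tail root, two paws.
MOUSE5 = Skeleton(
    names=("nose", "back", "tail_root", "paw_left", "paw_right"),
    edges=((1, 0), (1, 2), (1, 3), (1, 4)),
    center_index=1,
)
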