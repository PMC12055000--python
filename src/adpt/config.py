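"""Run configuration: geometry, thresholds, loss weights, training schedule.

One flat dataclass keeps every tunable in a single YAML-serializable place.
Defaults follow the reference training protocol for single-animal tasks
(190 epochs, 10 warm-up epochs, batch 8, AdamW with weight decay 1e-4,
warmup-cosine learning rate between 1e-5 and 1e-3, early stop after a
30-epoch plateau) and the published evaluation thresholds (confidence
cutoff 0.2, drift alpha 50 px for mice, identity change alpha 75 px).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["Config"]


@dataclass
class Config:
    # --- geometry -------------------------------------------------------
    global_scale: float = 1.0      # image resize factor applied before the network
    stride: int = 8                # input-to-head downscaling factor (power of two)
    sigma: float = 3.0             # heatmap Gaussian width, in head-map cells
    locref_radius: float = 0.0     # cells; 0 means "use 2 * sigma"
    limb_thickness: float = 2.0    # LRSS rasterization thickness, in head-map cells

    # --- decoding / identity -------------------------------------------
    conf_cutoff: float = 0.2       # confidence at or below this counts as a miss
    nms_radius: int = 5            # peak non-maximum suppression radius, head cells
    identity_radius: int = 3       # rho: identity-majority window radius, head cells
    n_identities: int = 1
    smoothing_window: int = 15     # temporal identity majority window, frames
    hysteresis: float = 10.0       # px margin before motion overrides raw identity

    # --- evaluation thresholds -----------------------------------------
    drift_alpha: float = 50.0      # px; per-keypoint drift threshold
    change_alpha: float = 75.0     # px; per-identity center change threshold

    # --- losses ---------------------------------------------------------
    w_heatmap: float = 1.0
    w_locref: float = 1.0
    w_lrss: float = 1.0
    w_baf: float = 1.0
    loss_kind: str = "rmse"        # "rmse" or "mse" for the regression heads

    # --- training schedule ----------------------------------------------
    epochs: int = 190
    warmup_epochs: int = 10
    iters_per_epoch: int = 0       # 0 means "one pass over the dataset"
    batch_size: int = 8
    lr_min: float = 1e-5
    lr_max: float = 1e-3
    weight_decay: float = 1e-4
    patience: int = 30             # early-stop plateau length, epochs
    monitor: str = "val"           # "val" (single-animal) or "train" (identity/social)
    val_fraction: float = 0.05

    # --- augmentation ranges (default mode) ------------------------------
    aug_rotation: float = 25.0     # degrees, symmetric
    aug_scale: tuple[float, float] = (0.9, 1.1)
    aug_translate_x: tuple[float, float] = (-20.0, 20.0)
    aug_translate_y: tuple[float, float] = (-20.0, 20.0)

    # --- mix-up ----------------------------------------------------------
    mixup_delta: float = 20.0      # foreground threshold on 8-bit intensities

    def __post_init__(self) -> None:
        if not 0 < self.global_scale <= 1:
            raise ValueError("global_scale must be in (0, 1]")
        if self.stride < 1 or (self.stride & (self.stride - 1)) != 0:
            raise ValueError("stride must be a power of two")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_identities < 1:
            raise ValueError("n_identities must be >= 1")

    @property
    def locref_supervision_radius(self) -> float:
        return self.locref_radius if self.locref_radius > 0 else 2.0 * self.sigma

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aug_scale"] = list(d["aug_scale"])
        d["aug_translate_x"] = list(d["aug_translate_x"])
        d["aug_translate_y"] = list(d["aug_translate_y"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("aug_scale", "aug_translate_x", "aug_translate_y"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)
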