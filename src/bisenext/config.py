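"""Configuration dataclasses for the network, decoder and training recipe."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VALID_OPS = ("DFEB", "EAMA", "Stem", "GE", "CE", "Conv")


@dataclass(frozen=True)
class StageSpec:
    """One operator row of a branch table.

    opr: operator tag; c: output channels; s: stride; r: repetitions;
    e: channel expansion factor (GE only).
    """

    opr: str
    c: int
    s: int = 1
    r: int = 1
    e: int = 1

    def __post_init__(self):
        if self.opr not in VALID_OPS:
            raise ValueError(f"unknown operator tag {self.opr!r}")
        if self.s not in (1, 2, 4):
            raise ValueError(f"stride must be 1, 2 or 4, got {self.s}")
        if self.r < 1 or self.c < 1 or self.e < 1:
            raise ValueError("c, r and e must be positive")


@dataclass(frozen=True)
class PointParams:
    """Point-refinement decoder parameters.

    j: oversampling multiplier; n: points per refinement step;
    beta: fraction of points taken from the uncertainty ranking;
    m: refinement iterations at inference.
    """

    j: int = 3
    n: int = 2048
    beta: float = 0.75
    m: int = 2

    def __post_init__(self):
        if self.j < 1 or self.n < 1 or self.m < 1:
            raise ValueError("j, n and m must be >= 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    @property
    def n_ranked(self) -> int:
        return int(self.beta * self.n)

    @property
    def n_random(self) -> int:
        return self.n - self.n_ranked


def detail_stages_dfeb(widths=(32, 64, 128, 128), use_eama: bool = True) -> list[StageSpec]:
    """Detail-branch layout with DFEB blocks (optionally interleaved EAMA).

    Stages S1-S3 end in a stride-2 DFEB; S4 keeps resolution (1/8 final).
    """
    c1, c2, c3, c4 = widths
    rows: list[StageSpec] = []
    for cin_stage, cout, last_stride in ((c1, c1, 2), (c1, c2, 2), (c2, c3, 2), (c3, c4, 1)):
        rows.append(StageSpec("DFEB", cout, 1))
        if use_eama:
            rows.append(StageSpec("EAMA", cout, 1))
        rows.append(StageSpec("DFEB", cout, last_stride))
    return rows


def detail_stages_plain(widths=(64, 64, 128)) -> list[StageSpec]:
    """Original bilateral-network detail branch: three conv stages to 1/8."""
    c1, c2, c3 = widths
    return [
        StageSpec("Conv", c1, 2), StageSpec("Conv", c1, 1),
        StageSpec("Conv", c2, 2), StageSpec("Conv", c2, 1, r=2),
        StageSpec("Conv", c3, 2), StageSpec("Conv", c3, 1, r=2),
    ]


def semantic_stages_default(widths=(16, 32, 64, 128), e: int = 6) -> list[StageSpec]:
    c0, c1, c2, c3 = widths
    return [
        StageSpec("Stem", c0, 4),
        StageSpec("GE", c1, 2, e=e), StageSpec("GE", c1, 1, e=e),
        StageSpec("GE", c2, 2, e=e), StageSpec("GE", c2, 1, e=e),
        StageSpec("GE", c3, 2, e=e), StageSpec("GE", c3, 1, r=3, e=e),
        StageSpec("CE", c3, 1),
    ]


@dataclass
class NetworkConfig:
    """Full network description.

    The default corresponds to the 512x512, 3-class configuration with all
    three novel modules enabled.  ``use_dfeb``/``use_eama``/``use_pointrefine``
    toggle the ablation variants; ``width_mult`` shrinks every channel count
    (for CPU-scale experiments).
    """

    num_classes: int = 3
    input_size: int = 512
    use_dfeb: bool = True
    use_eama: bool = True
    use_pointrefine: bool = True
    eama_groups: int = 16
    point_params: PointParams = field(default_factory=PointParams)
    width_mult: float = 1.0
    # decoder head widths
    head_mid_plain: int = 1024     # dense head of the baseline decoder
    head_mid_point: int = 64       # coarse head feeding the point decoder
    point_fc_dim: int = 128
    point_mlp_hidden: int = 128
    point_mlp_layers: int = 3
    aux_head_mid: int = 128

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    def _scale(self, c: int) -> int:
        return max(1, int(round(c * self.width_mult)))

    @property
    def detail_widths(self) -> tuple[int, ...]:
        if self.use_dfeb:
            return tuple(self._scale(c) for c in (32, 64, 128, 128))
        return tuple(self._scale(c) for c in (64, 64, 128))

    @property
    def semantic_widths(self) -> tuple[int, ...]:
        return tuple(self._scale(c) for c in (16, 32, 64, 128))

    @property
    def agg_channels(self) -> int:
        return self._scale(128)

    @property
    def detail_stages(self) -> list[StageSpec]:
        if self.use_dfeb:
            return detail_stages_dfeb(self.detail_widths, self.use_eama)
        return detail_stages_plain(self.detail_widths)

    @property
    def semantic_stages(self) -> list[StageSpec]:
        return semantic_stages_default(self.semantic_widths)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        pp = d.get("point_params")
        if isinstance(pp, dict):
            d["point_params"] = PointParams(**pp)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainConfig:
    """SGD recipe: poly(0.9) decay from lr_init with a floor at lr_min."""

    lr_init: float = 1e-2
    lr_min: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seed: int = 0
    schedule: str = "poly"
    poly_power: float = 0.9
    point_loss_weight: float = 1.0
    aux_loss_weight: float = 1.0
    target_miou: float | None = None   # optional early stop once reached

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        for name in ("lr_init", "lr_min", "batch_size", "epochs", "momentum", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch; final epoch returns lr_min."""
        if self.epochs <= 1:
            return self.lr_min
        t = epoch / (self.epochs - 1)
        lr = self.lr_init * (1.0 - t) ** self.poly_power
        return max(lr, self.lr_min)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))
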