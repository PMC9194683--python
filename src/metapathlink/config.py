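"""Configuration dataclasses with defaults anchored to the method's
published hyperparameter study, plus YAML load/merge helpers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .metapath import DEFAULT_CATALOG

VARIANTS = ("full", "nb", "sm", "avg")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    hidden_dim: embedding width d (must be even: coordinates pair into
        complex numbers for the rotation encoder).
    heads: attention heads K in intra-metapath aggregation.
    attention_dim: width of the inter-metapath (semantic) attention space.
    neighbors: per-target cap on sampled metapath instances.
    layers: stacked aggregation layers L.
    """

    hidden_dim: int = 32
    heads: int = 6
    attention_dim: int = 64
    neighbors: int = 150
    layers: int = 2
    dropout: float = 0.5
    leaky_slope: float = 0.01
    metapaths: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_CATALOG.items()})

    def __post_init__(self) -> None:
        if self.hidden_dim % 2 != 0:
            raise ValueError("hidden_dim must be even (complex coordinate pairing)")
        if self.heads < 1 or self.layers < 1 or self.neighbors < 1:
            raise ValueError("heads, layers and neighbors must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainingConfig:
    """Optimisation protocol: 1:1 negative sampling, 8:1:1 split, Adam,
    dropout 0.5, early stopping, at most 100 epochs."""

    neg_ratio: float = 1.0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    learning_rate: float = 0.005
    weight_decay: float = 0.001
    epochs: int = 100
    patience: int = 10
    min_epochs: int = 50
    seed: int = 0
    variant: str = "full"
    resample_each_epoch: bool = True
    remove_heldout_edges: bool = True

    def __post_init__(self) -> None:
        self.split = tuple(self.split)  # type: ignore[assignment]
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None
                ) -> tuple[ModelConfig, TrainingConfig]:
    """Build configs from an optional YAML file and dotted-key overrides.

    Precedence: overrides > file > defaults. Keys may be flat
    (``learning_rate``) or dotted (``model.hidden_dim``).
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    model_kw = dict(raw.get("model", {}))
    train_kw = dict(raw.get("training", {}))
    model_fields = {f.name for f in fields(ModelConfig)}
    train_fields = {f.name for f in fields(TrainingConfig)}
    for key, val in raw.items():
        if key in ("model", "training"):
            continue
        _route(key, val, model_kw, train_kw, model_fields, train_fields)
    for key, val in (overrides or {}).items():
        if key.startswith("model."):
            model_kw[key[6:]] = val
        elif key.startswith("training."):
            train_kw[key[9:]] = val
        else:
            _route(key, val, model_kw, train_kw, model_fields, train_fields)
    return ModelConfig(**model_kw), TrainingConfig(**train_kw)


def _route(key: str, val: Any, model_kw: dict, train_kw: dict,
           model_fields: set, train_fields: set) -> None:
    if key in model_fields:
        model_kw[key] = val
    elif key in train_fields:
        train_kw[key] = val
    else:
        raise KeyError(f"unknown configuration key {key!r}")


def dump_config(model: ModelConfig, training: TrainingConfig,
                path: str | Path) -> None:
    payload = {"model": asdict(model), "training": asdict(training)}
    payload["training"]["split"] = list(training.split)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
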