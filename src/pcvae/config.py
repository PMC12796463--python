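"""Run configuration: YAML loading with defaults merged in.

A run config has nested sections — ``simulate``, ``model``, ``train``,
``loss``, ``analysis`` — plus a root ``seed``. Partial files are fine: every
documented default is filled in, so an empty file is a valid full config.
All stage randomness is derived from the root seed (one split per stage) so
stages are independently reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from .losses import LossConfig
from .model import ModelConfig
from .simulate import (Distribution, HeterogeneitySpec, PhotophysicsSpec,
                       PRESETS, StructureModel)
from .train import TrainConfig

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "preset": "npc2d",
        "n_particles": None,        # None -> preset default
        "overrides": {},            # model / het / phys field overrides
    },
    "model": {
        "p": None,                  # None -> inferred from the data
        "d": 8,
        "encoder_widths": [64, 128, 1024],
        "decoder_fc_widths": [256, 512, 1024],
        "n_attention_heads": 4,
        "n_output_points": 128,
        "index_embed_dim": 32,
        "batchnorm": True,
    },
    "train": {
        "batch_size": 8,
        "epochs": 4,
        "learning_rate": 1e-4,
        "weight_decay": 1e-5,
    },
    "loss": {
        "beta_max": 1e-3,
        "warmup_steps": 5000,
    },
    "analysis": {
        "n_bins": 20,
        "registration": "rot_z",
        "grid_deg": 2.0,
        "ratios": [1.0, 0.5],
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Fully merged configuration plus per-stage seed derivation."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path=None, overrides: dict | None = None) -> "RunConfig":
        user: dict = {}
        if path is not None:
            with open(path) as f:
                user = yaml.safe_load(f) or {}
        merged = _deep_merge(DEFAULTS, user)
        if overrides:
            merged = _deep_merge(merged, overrides)
        return cls(raw=merged)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the root seed."""
        order = ["simulate", "train", "analysis", "robustness"]
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return int(children[order.index(stage)].generate_state(1)[0] % (2**31))

    def model_config(self, p: int) -> ModelConfig:
        section = self.raw["model"]
        return ModelConfig(
            p=int(section["p"] if section["p"] is not None else p),
            d=int(section["d"]),
            encoder_widths=tuple(section["encoder_widths"]),
            decoder_fc_widths=tuple(section["decoder_fc_widths"]),
            n_attention_heads=int(section["n_attention_heads"]),
            n_output_points=int(section["n_output_points"]),
            index_embed_dim=int(section["index_embed_dim"]),
            batchnorm=bool(section["batchnorm"]),
        )

    def loss_config(self) -> LossConfig:
        section = self.raw["loss"]
        return LossConfig(beta_max=float(section["beta_max"]),
                          warmup_steps=int(section["warmup_steps"]))

    def train_config(self) -> TrainConfig:
        section = self.raw["train"]
        return TrainConfig(
            batch_size=int(section["batch_size"]),
            epochs=int(section["epochs"]),
            learning_rate=float(section["learning_rate"]),
            weight_decay=float(section["weight_decay"]),
            seed=self.stage_seed("train"),
            loss=self.loss_config(),
        )

    def simulate_args(self) -> dict:
        section = self.raw["simulate"]
        preset = PRESETS[section["preset"]]
        overrides = section.get("overrides") or {}
        model = preset["model"]
        if "model" in overrides:
            model = StructureModel(**{**_structure_fields(model),
                                      **overrides["model"]})
        het = preset["het"] if "het" not in overrides \
            else _het_from_dict(overrides["het"])
        phys = preset["phys"]
        if "phys" in overrides:
            phys = PhotophysicsSpec(**{
                "dol": phys.dol,
                "mean_locs_per_site": phys.mean_locs_per_site,
                "loc_precision_nm": phys.loc_precision_nm,
                **overrides["phys"]})
        n = section["n_particles"] or preset["n_particles"]
        return dict(model=model, het=het, phys=phys, n_particles=int(n))


def _structure_fields(model: StructureModel) -> dict:
    return {"kind": model.kind, "radius_nm": model.radius_nm,
            "height_nm": model.height_nm, "base_edge_nm": model.base_edge_nm}


def _het_from_dict(spec: dict) -> HeterogeneitySpec:
    def dist(entry):
        if entry is None:
            return None
        return Distribution(kind=entry["kind"], a=float(entry.get("a", 0.0)),
                            b=float(entry.get("b", 0.0)))

    return HeterogeneitySpec(radius=dist(spec.get("radius")),
                             height=dist(spec.get("height")))
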