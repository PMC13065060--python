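"""Experiment configuration: one YAML file describing a full run.

The config nests the acquisition, augmentation, network and training
protocol dataclasses plus paths and seeds; ``load_config(save_config(c))``
is an exact round trip, field by field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .augment import AugmentParams
from .model import NetworkConfig
from .phantom import AcquisitionParams
from .training import TrainProtocol

__all__ = ["ExperimentConfig", "save_config", "load_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    data_dir: str = "data"
    output_dir: str = "runs"
    n_scans: int = 5
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    protocol: TrainProtocol = field(default_factory=TrainProtocol)
    seeds: tuple = (0, 1, 2)
    split_seed: int = 0


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
    return path


def _tupled(d: dict, keys) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    acq = AcquisitionParams(**_tupled(raw.pop("acquisition"), ["bin_edges_keV"]))
    net = NetworkConfig(**raw.pop("network"))
    proto_raw = raw.pop("protocol")
    aug_raw = _tupled(proto_raw.pop("augment"), ["brightness_range"])
    protocol = TrainProtocol(augment=AugmentParams(**aug_raw), **proto_raw)
    raw = _tupled(raw, ["seeds"])
    return ExperimentConfig(acquisition=acq, network=net, protocol=protocol,
                            **raw)
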