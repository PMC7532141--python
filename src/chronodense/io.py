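"""Configuration files, featurized-array archives and run manifests.

A single YAML file drives model + training + preprocessing; featurized
tensors are written as plain ``.npy`` files next to a JSON sidecar carrying
shapes and sampling metadata, which keeps reruns byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig
from .training import FitResult, TrainConfig

__all__ = [
    "load_config",
    "save_config",
    "save_archive",
    "load_archive",
    "write_history_csv",
    "RunManifest",
]


def load_config(path: str | Path) -> tuple[ModelConfig, TrainConfig, dict]:
    """Read ``{model: ..., train: ..., preprocess: ...}`` from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model = ModelConfig.from_dict(raw.get("model", {}))
    train = TrainConfig(**raw.get("train", {}))
    return model, train, raw.get("preprocess", {})


def save_config(path: str | Path, model: ModelConfig, train: TrainConfig,
                preprocess: dict | None = None) -> None:
    doc = {"model": model.to_dict(), "train": train.to_dict(),
           "preprocess": preprocess or {}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _catalog_hash(names) -> str:
    return hashlib.sha256("\n".join(map(str, names)).encode()).hexdigest()[:16]


def save_archive(path: str | Path, arrays: dict[str, np.ndarray],
                 metadata: dict | None = None) -> None:
    """Write arrays as ``<name>.npy`` plus ``sidecar.json`` (deterministic)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta["arrays"] = {name: list(a.shape) for name, a in arrays.items()}
    for name, a in arrays.items():
        np.save(path / f"{name}.npy", np.ascontiguousarray(a))
    (path / "sidecar.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_archive(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    sidecar = path / "sidecar.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"no sidecar.json under {path}")
    meta = json.loads(sidecar.read_text())
    arrays = {name: np.load(path / f"{name}.npy") for name in meta.get("arrays", {})}
    return arrays, meta


def write_history_csv(path: str | Path, result: FitResult) -> None:
    cols = ("epoch", "lr", "train_loss", "train_acc", "valid_loss", "valid_acc")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in result.history:
            writer.writerow([repr(row[c]) if isinstance(row[c], float) else row[c]
                             for c in cols])


@dataclass
class RunManifest:
    """Reproducibility record written into every CLI run directory."""

    command: str
    seed: int
    config_hash: str
    input_paths: list[str]
    output_paths: list[str]
    package_version: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @staticmethod
    def hash_config(model: ModelConfig, train: TrainConfig) -> str:
        blob = json.dumps({"model": model.to_dict(), "train": train.to_dict()},
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
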