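"""Manifest, configuration and checkpoint input/output.

The CSV manifest (columns path,label,client,country,split) is the single
source of dataset truth; images are lossless single-channel PNGs.  Run
configurations are YAML, schema-validated with unknown keys rejected.
Checkpoints are named-array archives carrying architecture id, config
hash, seed and stage metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .contrastive import ContrastiveConfig
from .denoising import DenoiseConfig
from .federated import FederationConfig
from .prototypes import ViewEnsembleConfig
from .synthetic import CLASS_NAMES, ClientShift, LabeledImage

LABEL_TO_ID = {name: i for i, name in enumerate(CLASS_NAMES)}
MANIFEST_COLUMNS = ("path", "label", "client", "country", "split")


@dataclass
class DataConfig:
    """Synthetic two-client federation layout (large repr client, small
    norepr client, ratio ~10:1 by default)."""

    repr_n_per_class: int = 500
    norepr_n_per_class: int = 50
    image_size: int = 64
    repr_country: str = "countryA"
    norepr_country: str = "countryB"
    repr_shift: ClientShift = field(default_factory=ClientShift)
    norepr_shift: ClientShift = field(
        default_factory=lambda: ClientShift(
            brightness_offset=0.08, contrast_gain=1.2, speckle_sigma=0.15
        )
    )


@dataclass
class RunConfig:
    mode: str = "proposed"
    seed: int = 0
    out_dir: str = "runs"
    noise_repr: float = 0.2
    noise_norepr: float = 0.2
    data: DataConfig = field(default_factory=DataConfig)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    views: ViewEnsembleConfig = field(default_factory=ViewEnsembleConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)


def _from_dict(cls, data: dict, path: str = ""):
    """Build a (possibly nested) dataclass, rejecting unknown keys with
    the offending field path in the error."""
    if not isinstance(data, dict):
        raise ValueError(f"{path or 'config'}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        here = f"{path}.{name}" if path else name
        target = _nested_type(cls, name)
        if target is not None:
            kwargs[name] = _from_dict(target, value, here)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or 'config'}: {exc}") from exc


_NESTED = {
    (RunConfig, "data"): DataConfig,
    (RunConfig, "contrastive"): ContrastiveConfig,
    (RunConfig, "denoise"): DenoiseConfig,
    (RunConfig, "views"): ViewEnsembleConfig,
    (RunConfig, "federation"): FederationConfig,
    (DataConfig, "repr_shift"): ClientShift,
    (DataConfig, "norepr_shift"): ClientShift,
}


def _nested_type(cls, name):
    from .contrastive import AugmentationSpec

    if (cls, name) in _NESTED:
        return _NESTED[(cls, name)]
    if name in ("augmentation", "aug"):
        return AugmentationSpec
    return None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)


def config_hash(cfg) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_dataset(images: list[LabeledImage], out_dir) -> Path:
    """Write PNGs plus the CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        rel = f"images/{im.client}_{i:05d}.png"
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / rel)
        rows.append(
            {
                "path": rel,
                "label": CLASS_NAMES[im.label],
                "client": im.client,
                "country": im.country,
                "split": im.split,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_manifest(path) -> list[LabeledImage]:
    """Load a manifest and its images; errors name the file and line."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    root = path.parent
    images = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["label"] not in LABEL_TO_ID:
            raise ValueError(f"{path}:{line}: unknown label {row['label']!r}")
        img_path = root / row["path"]
        if not img_path.exists():
            raise ValueError(f"{path}:{line}: image not found: {img_path}")
        arr = np.asarray(Image.open(img_path).convert("L"), dtype=np.float64) / 255.0
        images.append(
            LabeledImage(
                pixels=arr,
                label=LABEL_TO_ID[row["label"]],
                client=str(row["client"]),
                country=str(row["country"]),
                split=str(row["split"]),
            )
        )
    return images


def save_checkpoint(path, params: dict, metadata: dict) -> None:
    meta = json.dumps(metadata)
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **params)


def load_checkpoint(path):
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        params = {k: npz[k].copy() for k in npz.files if k != "__meta__"}
    return params, meta
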