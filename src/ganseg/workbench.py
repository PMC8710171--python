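"""Configuration, image and checkpoint I/O.

Run configuration is a flat YAML key-value file layered as
defaults < preset < file < command-line overrides.  Two presets exist:
``desk`` (64x64 phantoms, width-8 generator — trainable on one CPU) and
``paper`` (256x256, width-64 generator, 200 epochs — the full-scale
setting; expect GPU-scale runtimes elsewhere).

Images travel as 8- or 16-bit grayscale PNG; label maps as paletted
(indexed) PNG so class identities survive a round trip exactly.
Checkpoints are single ``.npz`` archives of every named parameter array
plus BN statistics, RNG state, counters and a checksummed JSON manifest.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .adversarial import DiscriminatorConfig
from .autodiff import Tensor
from .generator import GeneratorConfig
from .phantoms import ImageSample, PhantomSpec
from .training import TrainConfig, TrainState, init_state

__all__ = ["RunConfig", "load_config", "save_checkpoint", "load_checkpoint",
           "read_image_pair", "write_image_pair", "PRESETS", "CONFIG_KEYS"]

# label palette: background black, then distinct organ colors (classes 0-4)
_PALETTE = [(0, 0, 0), (220, 60, 60), (60, 120, 220), (60, 200, 120),
            (230, 200, 60)]

PRESETS: dict[str, dict] = {
    "desk": {
        "image_size": 64, "base_width": 8, "epochs": 30,
        "disc_widths": (16, 32, 64, 128, 256), "n_originals": 200,
    },
    "paper": {
        "image_size": 256, "base_width": 64, "epochs": 200,
        "disc_widths": (16, 32, 64, 128, 256), "n_originals": 780,
    },
}

_DEFAULTS = {
    "preset": "desk",
    "image_size": 64,
    "num_classes": 5,
    "base_width": 8,
    "block_counts": (3, 4, 6, 3),
    "use_batch_norm": True,
    "average_logits": True,
    "disc_widths": (16, 32, 64, 128, 256),
    "fc_width": 64,
    "include_image": False,
    "learning_rate": 0.01,
    "epochs": 30,
    "batch_size": 10,
    "k": 6,
    "lam": 0.2,
    "seed": 0,
    "init_stddev": 0.02,
    "deterministic": False,
    "pixel_reduction": "mean",
    "loss_gain": 32.0,
    "n_originals": 200,
    "split_fractions": (0.8, 0.1, 0.1),
    "expansion_factors": (4, 2, 2),
    "noise_std": 0.05,
    "bias_amplitude": 0.10,
    "dataset_dir": "dataset",
    "output_dir": "runs",
    "float32": True,
}

CONFIG_KEYS = frozenset(_DEFAULTS)
_TUPLE_KEYS = {"block_counts", "disc_widths", "split_fractions",
               "expansion_factors"}


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __getattr__(self, key):
        values = object.__getattribute__(self, "values")
        if key in values:
            return values[key]
        raise AttributeError(key)

    @property
    def dtype(self):
        return np.float32 if self.values["float32"] else np.float64

    def generator_config(self) -> GeneratorConfig:
        v = self.values
        return GeneratorConfig(
            in_channels=1, num_classes=v["num_classes"],
            base_width=v["base_width"],
            block_counts=tuple(v["block_counts"]),
            use_batch_norm=v["use_batch_norm"],
            average_logits=v["average_logits"], dtype=self.dtype)

    def discriminator_config(self) -> DiscriminatorConfig:
        v = self.values
        return DiscriminatorConfig(
            in_channels=v["num_classes"] - 1,
            conv_widths=tuple(v["disc_widths"]), fc_width=v["fc_width"],
            input_size=v["image_size"], include_image=v["include_image"],
            dtype=self.dtype)

    def train_config(self) -> TrainConfig:
        v = self.values
        return TrainConfig(
            learning_rate=v["learning_rate"], epochs=v["epochs"],
            batch_size=v["batch_size"], k=v["k"], lam=v["lam"],
            seed=v["seed"], init_stddev=v["init_stddev"],
            deterministic=v["deterministic"],
            pixel_reduction=v["pixel_reduction"],
            loss_gain=v["loss_gain"])

    def phantom_spec(self) -> PhantomSpec:
        v = self.values
        return PhantomSpec(image_size=v["image_size"],
                           noise_std=v["noise_std"],
                           bias_amplitude=v["bias_amplitude"],
                           seed=v["seed"])


def _validate(overrides: dict, source: str) -> None:
    for key, value in overrides.items():
        if key not in CONFIG_KEYS:
            raise KeyError(f"unknown configuration key {key!r} in {source}")
        default = _DEFAULTS[key]
        if key in _TUPLE_KEYS:
            if not isinstance(value, (list, tuple)):
                raise TypeError(f"{key} must be a sequence ({source})")
        elif isinstance(default, bool):
            if not isinstance(value, bool):
                raise TypeError(f"{key} must be a boolean ({source})")
        elif isinstance(default, (int, float)) and not isinstance(
                value, (int, float)):
            raise TypeError(f"{key} must be numeric ({source})")


def load_config(path: str | Path | None = None, preset: str | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Layer defaults < preset < file < overrides into a RunConfig."""
    values = dict(_DEFAULTS)
    file_values: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        file_values = yaml.safe_load(p.read_text()) or {}
        if not isinstance(file_values, dict):
            raise TypeError("config file must be a flat key: value mapping")
        _validate(file_values, str(p))
    preset = preset or file_values.get("preset") or values["preset"]
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from "
                       f"{sorted(PRESETS)}")
    values.update(PRESETS[preset])
    values["preset"] = preset
    values.update(file_values)
    if overrides:
        overrides = {k: v for k, v in overrides.items() if v is not None}
        _validate(overrides, "command line")
        values.update(overrides)
    for key in _TUPLE_KEYS:
        values[key] = tuple(values[key])
    return RunConfig(values)


# -- checkpoints --------------------------------------------------------------

def _arrays_checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_checkpoint(state: TrainState, path: str | Path,
                    run_config: RunConfig | None = None) -> None:
    """Archive every named array, counters, RNG state and a manifest."""
    arrays: dict[str, np.ndarray] = {}
    for name, t in state.gen_params.items():
        arrays[f"gen/{name}"] = t.data
    for name, t in state.disc_params.items():
        arrays[f"disc/{name}"] = t.data
    for name, stats in state.gen_state.items():
        arrays[f"bn/{name}/mean"] = stats["mean"]
        arrays[f"bn/{name}/var"] = stats["var"]
    manifest = {
        "epoch": state.epoch,
        "n_disc_updates": state.n_disc_updates,
        "n_gen_updates": state.n_gen_updates,
        "train_config": asdict(state.cfg),
        "gen_config": {**asdict(state.gen_cfg),
                       "dtype": np.dtype(state.gen_cfg.dtype).name},
        "disc_config": {**asdict(state.disc_cfg),
                        "dtype": np.dtype(state.disc_cfg.dtype).name},
        "run_config": run_config.values if run_config else None,
        "rng_state": json.loads(json.dumps(
            state.rng.bit_generator.state, default=int)),
        "history_tail": state.history[-50:],
        "checksum": _arrays_checksum(arrays),
    }
    buf = io.BytesIO()
    np.savez(buf, manifest=json.dumps(manifest), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> TrainState:
    """Restore a TrainState; raises on checksum mismatch."""
    try:
        with np.load(Path(path), allow_pickle=False) as npz:
            manifest = json.loads(str(npz["manifest"]))
            arrays = {k: npz[k] for k in npz.files if k != "manifest"}
    except (ValueError, OSError):
        raise
    except Exception as exc:  # zip/json corruption surfaces many ways
        raise ValueError(
            f"checkpoint {path} is unreadable or corrupt: {exc}") from exc
    if _arrays_checksum(arrays) != manifest["checksum"]:
        raise ValueError(f"checkpoint {path} failed its integrity check")
    gcd = dict(manifest["gen_config"])
    gcd["dtype"] = np.dtype(gcd["dtype"]).type
    gcd["block_counts"] = tuple(gcd["block_counts"])
    gen_cfg = GeneratorConfig(**gcd)
    dcd = dict(manifest["disc_config"])
    dcd["dtype"] = np.dtype(dcd["dtype"]).type
    dcd["conv_widths"] = tuple(dcd["conv_widths"])
    disc_cfg = DiscriminatorConfig(**dcd)
    cfg = TrainConfig(**manifest["train_config"])
    state = init_state(gen_cfg, disc_cfg, cfg)
    for name, t in state.gen_params.items():
        t.data = arrays[f"gen/{name}"].astype(gen_cfg.dtype)
    for name, t in state.disc_params.items():
        t.data = arrays[f"disc/{name}"].astype(disc_cfg.dtype)
    for name, stats in state.gen_state.items():
        stats["mean"] = arrays[f"bn/{name}/mean"]
        stats["var"] = arrays[f"bn/{name}/var"]
    state.epoch = manifest["epoch"]
    state.n_disc_updates = manifest["n_disc_updates"]
    state.n_gen_updates = manifest["n_gen_updates"]
    state.history = list(manifest["history_tail"])
    state.rng.bit_generator.state = manifest["rng_state"]
    return state


# -- image I/O ----------------------------------------------------------------

def write_image_pair(sample: ImageSample, img_path: str | Path,
                     label_path: str | Path, bits: int = 8) -> None:
    """Write the grayscale image (8/16-bit PNG) and indexed-palette label PNG."""
    img = np.clip(sample.image, 0.0, 1.0)
    if bits == 8:
        Image.fromarray((img * 255).round().astype(np.uint8), "L").save(img_path)
    elif bits == 16:
        Image.fromarray((img * 65535).round().astype(np.uint16)).save(img_path)
    else:
        raise ValueError("bits must be 8 or 16")
    lab = Image.fromarray(sample.label.astype(np.uint8), "P")
    palette = []
    for rgb in _PALETTE:
        palette.extend(rgb)
    lab.putpalette(palette)
    lab.save(label_path)


def read_image_pair(img_path: str | Path, label_path: str | Path,
                    num_classes: int = 5) -> ImageSample:
    """Read a PNG pair back; image scaled to [0, 1] by its bit depth."""
    with Image.open(img_path) as im:
        if im.mode == "I;16" or im.mode == "I":
            image = np.asarray(im, dtype=np.float64) / 65535.0
        elif im.mode == "L":
            image = np.asarray(im, dtype=np.float64) / 255.0
        else:
            raise ValueError(f"{img_path}: expected grayscale PNG, got mode "
                             f"{im.mode}")
    with Image.open(label_path) as lm:
        label = np.asarray(lm.convert("P"), dtype=np.int64)
    if image.shape != label.shape:
        raise ValueError(f"image {image.shape} and label {label.shape} "
                         "sizes differ")
    bad = label >= num_classes
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"label value {label[r, c]} >= K={num_classes} "
                         f"at pixel ({r}, {c}) in {label_path}")
    return ImageSample(image=image, label=label,
                       sample_id=Path(img_path).stem, phantom_index=-1)
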