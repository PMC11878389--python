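"""Pipeline plumbing: configuration, manifests, tensors, end-to-end runs.

The full screening pipeline is: generate a labeled synthetic bank, simulate
hand-held captures (optional), rectify each capture into the canonical
frame, derive the examiner-oracle contour and the hue plane, train the CNN
on the train split, predict the held-out split, and report the confusion
matrix with screening metrics.  Every stage draws its randomness from one
integer seed through counter-based seed spawning, so two runs with the same
config produce byte-identical reports.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml
from PIL import Image

from . import cnn, contour, evaluate, rectify, synth
from .synth import CLASS_ORDER, ClassLabel, SurfaceParams

MANIFEST_COLUMNS = ["file", "label", "variant", "split", "seed"]


class ManifestError(ValueError):
    pass


def write_manifest(rows: List[dict], path) -> None:
    """Tab-separated manifest; known columns first, extras preserved."""
    extras = sorted({k for r in rows for k in r} - set(MANIFEST_COLUMNS))
    cols = MANIFEST_COLUMNS + extras
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        w.writeheader()
        for r in rows:
            w.writerow(r)


def read_manifest(path) -> List[dict]:
    """Lossless TSV round trip; malformed rows report their line number."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"manifest missing columns {missing}")
        for lineno, r in enumerate(reader, start=2):
            if any(v is None for v in r.values()) or None in r:
                raise ManifestError(f"malformed manifest row at line {lineno}")
            rows.append(dict(r))
    return rows


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full run bit-identically."""

    seed: int = 0
    # bank composition (study conditions: 1,172 images, 240/class train)
    per_class_counts: dict = field(
        default_factory=lambda: {
            "SPHERICAL": 275,
            "SYMMETRIC": 302,
            "ASYMMETRIC": 295,
            "IRREGULAR": 300,
        }
    )
    train_per_class: int = synth.TRAIN_PER_CLASS
    grid_n: int = synth.CANONICAL_N
    # capture simulation (0 disables the distort/rectify stage)
    capture_jitter_px: float = 8.0
    # classifier
    input_size: int = 64
    channels: int = 2  # contour mask + hue; 1 = mask only
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-2
    momentum: float = 0.9
    train_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ManifestError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def cnn_spec(self) -> cnn.CnnSpec:
        return cnn.CnnSpec(input_size=self.input_size, channels=self.channels)

    def train_config(self) -> cnn.TrainConfig:
        return cnn.TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            seed=self.train_seed,
        )


# ---------------------------------------------------------------------------
# Tensor construction
# ---------------------------------------------------------------------------

ORACLE_GRID_N = 128  # contour extraction grid; half canonical is ample


def hue_plane(image_rgb: np.ndarray, out_n: int) -> np.ndarray:
    """Normalized hue of a topogram, 0 where achromatic (overlay/background)."""
    import skimage.transform

    small = skimage.transform.resize(
        image_rgb.astype(float) / 255.0, (out_n, out_n, 3), order=1, anti_aliasing=True
    )
    hsv = rectify.rgb_to_hsv(np.clip(np.round(small * 255), 0, 255).astype(np.uint8))
    hue = hsv[..., 0] / 360.0
    chromatic = (hsv[..., 1] > 0.2) & (hsv[..., 2] > 0.15)
    return np.where(chromatic, hue, 0.0)


def build_example(
    image_rgb: np.ndarray, params: SurfaceParams, input_size: int = 64, channels: int = 2
) -> np.ndarray:
    """(channels, n, n) float32 classifier input for one topogram."""
    pm = synth.make_power_map(params, grid_n=ORACLE_GRID_N)
    c = contour.oracle_contour(pm)
    mask = contour.rasterize(c, input_size, thickness_px=1, fill=True)
    planes = [mask.astype(np.float32)]
    if channels == 2:
        planes.append(hue_plane(image_rgb, input_size).astype(np.float32))
    return np.stack(planes)


def _capture_and_rectify(image: np.ndarray, jitter_px: float, rng_seed: int) -> np.ndarray:
    topo = synth.Topogram(image=image, zones_px=(), sidecar={})
    cap, quad = synth.distort_capture(topo, corner_jitter_px=jitter_px, rng_seed=rng_seed)
    return rectify.warp_to_canonical(cap, quad, n=image.shape[0])


def dataset_from_bank(
    bank_dir,
    rows: Optional[List[dict]] = None,
    input_size: int = 64,
    channels: int = 2,
    capture_jitter_px: float = 0.0,
    seed: int = 0,
) -> dict:
    """Load a generated bank into train/test tensors.

    When ``capture_jitter_px`` > 0 each topogram passes through a seeded
    simulated capture and is rectified with the true corner quad before the
    hue plane is extracted, exercising the capture-time path.
    """
    bank_dir = Path(bank_dir)
    if rows is None:
        rows = read_manifest(bank_dir / "manifest.tsv")
    xs = {"train": [], "test": []}
    ys = {"train": [], "test": []}
    for i, r in enumerate(rows):
        sidecar = json.loads((bank_dir / r["file"]).with_suffix(".json").read_text())
        params = SurfaceParams.from_dict(sidecar["params"])
        img = np.asarray(Image.open(bank_dir / r["file"]).convert("RGB"))
        if capture_jitter_px > 0:
            cap_seed = int(
                np.random.SeedSequence(seed, spawn_key=(7, i)).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            img = _capture_and_rectify(img, capture_jitter_px, cap_seed)
        xs[r["split"]].append(build_example(img, params, input_size, channels))
        ys[r["split"]].append(CLASS_ORDER.index(ClassLabel(r["label"])))
    return {
        "train_x": np.stack(xs["train"]) if xs["train"] else np.zeros((0,)),
        "train_y": np.asarray(ys["train"], dtype=int),
        "test_x": np.stack(xs["test"]) if xs["test"] else np.zeros((0,)),
        "test_y": np.asarray(ys["test"], dtype=int),
    }


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def run_end_to_end(cfg: PipelineConfig, out_dir) -> dict:
    """Full pipeline; writes manifest, model, report.json; returns the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bank_dir = out_dir / "bank"
    counts = {ClassLabel(k): v for k, v in cfg.per_class_counts.items()}
    rows = synth.generate_bank(
        counts,
        seed=cfg.seed,
        out_dir=bank_dir,
        grid_n=cfg.grid_n,
        train_per_class=cfg.train_per_class,
    )
    data = dataset_from_bank(
        bank_dir,
        rows,
        input_size=cfg.input_size,
        channels=cfg.channels,
        capture_jitter_px=cfg.capture_jitter_px,
        seed=cfg.seed,
    )
    model = cnn.build_model(cfg.cnn_spec(), seed=cfg.train_seed)
    model, curve = cnn.train(
        model, data["train_x"], data["train_y"], data["test_x"], data["test_y"],
        cfg.train_config(),
    )
    model.save(out_dir / "model.npz")
    pred_idx, _ = cnn.predict(model, data["test_x"])
    pred = [CLASS_ORDER[i].value for i in np.atleast_1d(pred_idx)]
    truth = [CLASS_ORDER[i].value for i in data["test_y"]]
    rep = evaluate.report(evaluate.confusion_matrix(pred, truth))
    rep["split_sizes"] = {"train": int(len(data["train_y"])), "test": int(len(data["test_y"]))}
    rep["epoch_curve"] = {
        "train_acc": [round(a, 4) for a in curve.train_acc],
        "test_acc": [round(a, 4) for a in curve.test_acc],
        "mean_test_acc": round(curve.mean_test_acc(), 4),
    }
    rep["config"] = cfg.to_dict()
    rep["config_digest"] = cfg.digest()
    text = json.dumps(rep, indent=1, sort_keys=True)
    (out_dir / "report.json").write_text(text)
    rep["report_digest"] = hashlib.sha256(text.encode()).hexdigest()
    return rep
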