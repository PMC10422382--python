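"""Deep-feature extraction with modified CNN backbones.

A "modified" backbone is the published architecture with its 1000-class
output layer removed and replaced by a new fully connected layer with one
unit per disease class (five by default), trained with SGD on the
softmax cross-entropy. Features are exported from the global-average-pool
layer, giving an N x 2048 table for ResNet-50, N x 1920 for DenseNet-201
and N x 2048 for InceptionV3.

No pretrained ImageNet weights ship with this package: convolutional
weights are a fixed, seeded He-initialized basis and only the new head is
trained (a linear probe on frozen convolutional features). Images are
resized to the backbone input size, grayscale replicated to three
channels, scaled to [0, 1] and standardized with the usual ImageNet
channel statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import backbones as _bb
from .dataset_io import ImageManifest
from .nn import Sequential, weights_checksum

__all__ = [
    "BackboneSpec",
    "TrainConfig",
    "FeatureTable",
    "ModifiedBackbone",
    "build_modified_backbone",
    "finetune",
    "extract_features",
    "load_image_batch",
]

_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: tuple[int, int, int] = (224, 224, 3)
    pretrained: bool = False
    num_classes: int = 5
    feature_layer: str = "global_average_pool"
    weight_seed: int = 0

    def __post_init__(self):
        if self.name not in _bb.SUPPORTED_BACKBONES:
            raise ValueError(
                f"unsupported backbone {self.name!r}; supported: "
                f"{', '.join(_bb.SUPPORTED_BACKBONES)}"
            )
        if self.pretrained:
            raise ValueError(
                "pretrained ImageNet weights are not distributed with this "
                "package; use pretrained=False (seeded random convolutional "
                "basis with a trained head)"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    """Head-training schedule (SGD on softmax cross-entropy)."""

    epochs: int = 100
    learning_rate: float = 1e-4  # 1e-5 also used in the field for this task
    minibatch: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")


@dataclass
class FeatureTable:
    """N x d deep-feature matrix with integer labels and provenance."""

    matrix: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.matrix.shape[1]

    def select(self, indices) -> "FeatureTable":
        """Column subset, preserving labels and provenance lineage."""
        idx = np.asarray(sorted(indices), dtype=np.int64)
        prov = dict(self.provenance)
        prov["selected_indices"] = idx.tolist()
        return FeatureTable(self.matrix[:, idx], self.labels.copy(), prov)

    def save(self, path: str | Path) -> None:
        """Delimited table ``label,f0001..f<d>`` plus a JSON metadata sidecar."""
        path = Path(path)
        d = self.feature_dim
        width = max(4, len(str(d)))
        header = "label," + ",".join(f"f{i + 1:0{width}d}" for i in range(d))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(
                    str(int(lab)) + ","
                    + ",".join(repr(float(v)) for v in row) + "\n"
                )
        meta = dict(self.provenance)
        meta.update(n_samples=self.n_samples, feature_dim=d)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        prov = {}
        if meta_path.exists():
            prov = json.loads(meta_path.read_text(encoding="utf-8"))
            prov.pop("n_samples", None)
            prov.pop("feature_dim", None)
        return cls(data[:, 1:], data[:, 0].astype(np.int64), prov)


class ModifiedBackbone:
    """A feature network plus a new, trainable FC softmax head."""

    def __init__(self, spec: BackboneSpec, feature_net: Sequential):
        self.spec = spec
        self.feature_net = feature_net
        self.feature_dim = _bb.FEATURE_WIDTHS[spec.name]
        self.trained = False
        # head: logits = (x - mu) / sigma @ W + b
        self.head_W = np.zeros((self.feature_dim, spec.num_classes))
        self.head_b = np.zeros(spec.num_classes)
        self._norm_mu = np.zeros(self.feature_dim)
        self._norm_sigma = np.ones(self.feature_dim)

    def backbone_checksum(self) -> str:
        return weights_checksum(self.feature_net)

    def replace_head(self, num_classes: int) -> None:
        """Head surgery: new FC layer, convolutional weights untouched."""
        self.spec = BackboneSpec(
            self.spec.name, self.spec.input_size, self.spec.pretrained,
            num_classes, self.spec.feature_layer, self.spec.weight_seed,
        )
        self.head_W = np.zeros((self.feature_dim, num_classes))
        self.head_b = np.zeros(num_classes)
        self.trained = False

    def pooled_features(self, batch: np.ndarray) -> np.ndarray:
        """Global-average-pool activations for an (N, H, W, 3) float batch."""
        x = np.transpose(batch, (0, 3, 1, 2)).astype(np.float32)
        return self.feature_net.forward(x).astype(np.float64)

    def logits(self, pooled: np.ndarray) -> np.ndarray:
        z = (pooled - self._norm_mu) / self._norm_sigma
        return z @ self.head_W + self.head_b

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(self.pooled_features(batch)), axis=1)


def build_modified_backbone(spec: BackboneSpec) -> ModifiedBackbone:
    """Instantiate the architecture and attach a fresh ``num_classes`` head."""
    net = _bb.build_feature_net(spec.name, spec.weight_seed)
    return ModifiedBackbone(spec, net)


def _load_image(path, size_hw: tuple[int, int]) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((size_hw[1], size_hw[0]), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc
    return (arr - _IMAGENET_MEAN) / _IMAGENET_STD


def load_image_batch(paths, input_size=(224, 224, 3)) -> np.ndarray:
    """(N, H, W, 3) standardized float batch from image files."""
    h, w = input_size[0], input_size[1]
    return np.stack([_load_image(p, (h, w)) for p in paths])


def _manifest_pooled(model: ModifiedBackbone, manifest: ImageManifest,
                     batch_size: int = 8) -> np.ndarray:
    paths = [r.path for r in manifest.records]
    out = []
    for i in range(0, len(paths), batch_size):
        batch = load_image_batch(paths[i:i + batch_size], model.spec.input_size)
        out.append(model.pooled_features(batch))
    return np.vstack(out)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def finetune(model: ModifiedBackbone, manifest: ImageManifest,
             cfg: TrainConfig) -> tuple[ModifiedBackbone, list[float]]:
    """Train the softmax head by minibatch SGD on the manifest's train split.

    The convolutional feature basis stays frozen; pooled features are
    z-scored with train-split statistics before the head. Returns the model
    and the per-epoch mean cross-entropy loss history.
    """
    train = manifest.subset("train")
    if len(train) == 0:
        raise ValueError("manifest has no records assigned to the train split")
    X = _manifest_pooled(model, train)
    y = train.labels()
    k = model.spec.num_classes
    if y.max() >= k:
        raise ValueError("manifest has more classes than the model head")

    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    model._norm_mu, model._norm_sigma = mu, sigma
    Z = (X - mu) / sigma

    rng = np.random.default_rng(cfg.seed)
    W, b = model.head_W, model.head_b
    n = len(y)
    onehot = np.eye(k)[y]
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.minibatch):
            idx = order[start:start + cfg.minibatch]
            zb, yb = Z[idx], onehot[idx]
            p = _softmax(zb @ W + b)
            eps = 1e-12
            epoch_loss += -np.sum(np.log(p[np.arange(len(idx)), y[idx]] + eps))
            g = (p - yb) / len(idx)
            W -= cfg.learning_rate * (zb.T @ g)
            b -= cfg.learning_rate * g.sum(axis=0)
        history.append(epoch_loss / n)
    model.trained = True
    return model, history


def extract_features(model: ModifiedBackbone, manifest: ImageManifest,
                     allow_untrained: bool = True) -> FeatureTable:
    """Export global-average-pool features, one row per manifest record."""
    if not model.trained and not allow_untrained:
        raise ValueError("model is untrained; pass allow_untrained=True to override")
    X = _manifest_pooled(model, manifest)
    prov = {
        "backbone": model.spec.name,
        "feature_layer": model.spec.feature_layer,
        "weight_seed": model.spec.weight_seed,
        "trained": bool(model.trained),
        "backbone_checksum": model.backbone_checksum(),
        "class_names": list(manifest.class_names),
        "config_hash": hashlib.sha256(
            repr((model.spec, sorted(str(r.path) for r in manifest.records))).encode()
        ).hexdigest()[:16],
    }
    return FeatureTable(X, manifest.labels(), prov)
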