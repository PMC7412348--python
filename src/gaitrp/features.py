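"""Deep-feature extraction from RP images and SVM classification.

Three extractor backends share one contract (one fixed-length row per
image):

* ``alexnet-fc7`` — penultimate fully connected layer (4096-wide) of a
  pretrained AlexNet; optional, requires torch/torchvision + weights.
* ``tiny-cnn-test`` — a small fixed-weight convolutional network in pure
  numpy; deterministic, no download, used by the test suite.
* ``random-projection-test`` — seeded Gaussian projection of the raw
  pixels; the simplest deterministic reference backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import block_reduce
from skimage.transform import resize, resize_local_mean

from gaitrp.recurrence import RPImage

BACKENDS = ("alexnet-fc7", "tiny-cnn-test", "random-projection-test")


class FeatureBackendError(RuntimeError):
    """Raised when a backend is unavailable in the current environment."""


@dataclass(frozen=True)
class FeatureExtractorSpec:
    backend: str = "tiny-cnn-test"
    input_size: tuple[int, int, int] = (227, 227, 3)
    output_dim: int | None = None
    deterministic: bool = True
    weights_source: str = "seed:0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")

    def resolved_dim(self) -> int:
        if self.output_dim is not None:
            return self.output_dim
        if self.backend == "alexnet-fc7":
            return 4096
        if self.backend == "tiny-cnn-test":
            return _TinyCNN.OUTPUT_DIM
        return 128  # random projection default


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"
    kernel: str = "linear"
    multiclass_scheme: str = "one-vs-one"
    C: float = 1.0
    seed: int = 0
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.kind != "svm":
            raise ValueError("only SVM classifiers are supported")
        if self.kernel not in ("linear", "rbf", "poly", "sigmoid"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.multiclass_scheme not in ("one-vs-one", "one-vs-rest"):
            raise ValueError("multiclass_scheme must be one-vs-one or one-vs-rest")


@dataclass
class FeatureMatrix:
    """Samples x features with aligned labels and subject groups."""

    F: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        if not (len(self.F) == len(self.labels) == len(self.groups)):
            raise ValueError(
                "row count, label count and group count must match: "
                f"{len(self.F)}, {len(self.labels)}, {len(self.groups)}"
            )
        if self.F.size and not np.isfinite(self.F).all():
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return len(self.F)

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.F[mask], self.labels[mask], self.groups[mask], dict(self.meta)
        )


def prepare_input(image: RPImage, spec: FeatureExtractorSpec) -> np.ndarray:
    """Turn a gray-level image into a network-ready H x W x 3 tensor.

    Resizing uses the same bilinear settings as the RP image resampler,
    so both paths agree on shared inputs. The grayscale plane is
    replicated across the 3 channels; test backends apply identity
    normalization, the AlexNet backend applies ImageNet statistics.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    h, w, _ = spec.input_size
    if px.shape != (h, w):
        px = resize(px, (h, w), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
        px = np.clip(px, 0.0, 1.0)
    tensor = np.repeat(px[:, :, None], 3, axis=2)
    if spec.backend == "alexnet-fc7":
        mean = np.array([0.485, 0.456, 0.406])
        std = np.array([0.229, 0.224, 0.225])
        tensor = (tensor - mean) / std
    return tensor


class _TinyCNN:
    """Fixed-weight two-layer convolutional network in numpy.

    conv(8 @ 5x5) -> ReLU -> maxpool 2 -> conv(16 @ 3x3) -> ReLU ->
    maxpool 2 -> mean-pool 2 -> flatten. Weights are drawn once from a
    seeded generator; half of the first-layer filters are structured
    (multi-scale averages and oriented edges) so block-texture scale is
    captured, the rest are random.
    """

    INPUT_SIDE = 56
    OUTPUT_DIM = 16 * 14 * 14

    def __init__(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        f = []
        # structured filters: averages + oriented edge detectors
        box = np.ones((5, 5)) / 25.0
        f.append(box)
        f.append(-box)
        edge_v = np.zeros((5, 5)); edge_v[:, :2] = 1; edge_v[:, 3:] = -1
        f.append(edge_v / 10.0)
        f.append(edge_v.T / 10.0)
        for _ in range(4):
            k = rng.standard_normal((5, 5))
            f.append((k - k.mean()) / 5.0)
        self.w1 = np.stack(f)  # 8 x 5 x 5
        self.b1 = np.zeros(8)
        w2 = rng.standard_normal((16, 8, 3, 3))
        self.w2 = (w2 - w2.mean(axis=(1, 2, 3), keepdims=True)) / 8.0
        self.b2 = np.zeros(16)

    @staticmethod
    def _conv2d(planes: np.ndarray, kernels: np.ndarray, bias: np.ndarray):
        # planes: C_in x H x W, kernels: C_out x C_in x kh x kw (same-pad)
        from scipy.ndimage import correlate

        c_out = kernels.shape[0]
        out = np.empty((c_out, planes.shape[1], planes.shape[2]))
        for o in range(c_out):
            acc = np.zeros(planes.shape[1:])
            for c in range(planes.shape[0]):
                acc += correlate(planes[c], kernels[o, c], mode="nearest")
            out[o] = acc + bias[o]
        return out

    def forward(self, gray: np.ndarray) -> np.ndarray:
        x = resize_local_mean(gray, (self.INPUT_SIDE, self.INPUT_SIDE))
        h = self._conv2d(x[None], self.w1[:, None], self.b1)
        h = np.maximum(h, 0.0)
        h = block_reduce(h, (1, 2, 2), np.max)  # 8 x 28 x 28
        h = self._conv2d(h, self.w2, self.b2)
        h = np.maximum(h, 0.0)
        h = block_reduce(h, (1, 2, 2), np.max)  # 16 x 14 x 14
        return h.ravel()


_TINY_CACHE: dict[int, _TinyCNN] = {}


def _weights_seed(spec: FeatureExtractorSpec) -> int:
    src = spec.weights_source
    if src.startswith("seed:"):
        return int(src.split(":", 1)[1])
    return spec.seed


def extract_features(
    images: list[RPImage], spec: FeatureExtractorSpec
) -> np.ndarray:
    """Extract one feature row per image; rows stack in input order."""
    if not images:
        raise ValueError("empty image list")
    if spec.backend == "alexnet-fc7":
        return _extract_alexnet(images, spec)
    if spec.backend == "tiny-cnn-test":
        seed = _weights_seed(spec)
        net = _TINY_CACHE.get(seed)
        if net is None:
            net = _TINY_CACHE[seed] = _TinyCNN(seed)
        rows = [net.forward(prepare_input(im, spec)[:, :, 0]) for im in images]
        return np.stack(rows)
    # random-projection-test
    dim = spec.resolved_dim()
    h, w, _ = spec.input_size
    rng = np.random.default_rng(spec.seed)
    proj = rng.standard_normal((h * w, dim)) / np.sqrt(h * w)
    flat = np.stack(
        [prepare_input(im, spec)[:, :, 0].ravel() for im in images]
    )
    return flat @ proj


def _extract_alexnet(images: list[RPImage], spec: FeatureExtractorSpec):
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise FeatureBackendError(
            "backend 'alexnet-fc7' requires torch and torchvision with "
            "pretrained weights (network download). Offline alternatives: "
            "'tiny-cnn-test' or 'random-projection-test'."
        ) from exc
    import torch
    from torchvision.models import alexnet, AlexNet_Weights

    model = alexnet(weights=AlexNet_Weights.IMAGENET1K_V1)
    model.eval()
    # truncate at the penultimate fully connected layer (fc7 activations)
    model.classifier = torch.nn.Sequential(*list(model.classifier.children())[:5])
    rows = []
    with torch.no_grad():
        for im in images:
            t = prepare_input(im, spec)
            t = torch.from_numpy(np.ascontiguousarray(t.transpose(2, 0, 1)))
            rows.append(model(t.unsqueeze(0).float()).numpy().ravel())
    return np.stack(rows)


def train_classifier(fm: FeatureMatrix, spec: ClassifierSpec):
    """Train an SVM on a feature matrix; deterministic given spec.seed."""
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    classes = np.unique(fm.labels)
    if len(classes) < 2:
        raise ValueError(
            f"need at least 2 classes to train, got {list(classes)}"
        )
    svc = SVC(
        kernel=spec.kernel,
        C=spec.C,
        decision_function_shape=(
            "ovo" if spec.multiclass_scheme == "one-vs-one" else "ovr"
        ),
        random_state=spec.seed,
    )
    model = Pipeline([("scale", StandardScaler()), ("svm", svc)]) if spec.zscore else svc
    model.fit(fm.F, fm.labels)
    model.n_features_expected_ = fm.F.shape[1]
    return model


def predict(model, F: np.ndarray) -> np.ndarray:
    """Predict one label per feature row; deterministic."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.size == 0:
        return np.asarray([], dtype=object)
    expected = getattr(model, "n_features_expected_", F.shape[1])
    if F.shape[1] != expected:
        raise ValueError(
            f"feature width {F.shape[1]} does not match training width {expected}"
        )
    return model.predict(F)


def decision_scores(model, F: np.ndarray) -> np.ndarray | None:
    """Binary decision-function scores when available (for rank AUC)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    try:
        scores = model.decision_function(F)
    except (AttributeError, ValueError):
        return None
    return scores if scores.ndim == 1 else None
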