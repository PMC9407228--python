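"""The CropNet-bX-Ymm 3-D patch classifier family.

CropNet-bX-Ymm is a contracting CNN over an isotropically sampled cubic ROI
with edge Y mm (1 mm^3 voxels): each resolution level applies X blocks of
(3x3x3 convolution -> ReLU -> dropout), levels are joined by 2x max-pooling,
and the final level is flattened into a single sigmoid unit giving the
probability that the ROI contains a metastasis.  The default width schedule
(64, 128, 256, 512) puts the teacher CropNet-b2-16mm at ~14M and the student
CropNet-b4-16mm at ~33M trainable parameters; the student's larger capacity
is what lets it absorb the pseudo-labeled corpus.

Dropout doubles as the model-noising mechanism: it is active only in training
mode, so inference is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _engine as eng
from .errors import DimensionError

__all__ = ["ModelSpec", "Classifier", "build_model", "count_parameters"]

DEFAULT_WIDTHS = (64, 128, 256, 512)
#: CPU-friendly schedule used by the desk-scale experiments and the test suite.
DESK_WIDTHS = (8, 16, 32, 64)


@dataclass(frozen=True)
class ModelSpec:
    """CropNet-bX-Ymm hyperparameters.

    ``blocks_per_level`` is the X of the model name, ``roi_edge_mm`` the Y.
    ``roi_edge_mm`` must be divisible by ``2**(levels - 1)`` so every
    max-pooling halving lands on an integer grid.
    """

    blocks_per_level: int
    roi_edge_mm: int = 16
    levels: int = 4
    widths: tuple[int, ...] = DEFAULT_WIDTHS
    dropout_rate: float = 0.15
    kernel_edge: int = 3

    def __post_init__(self) -> None:
        if self.blocks_per_level < 1:
            raise ValueError("blocks_per_level must be >= 1")
        if len(self.widths) != self.levels:
            raise ValueError("need one width per resolution level")
        if self.roi_edge_mm % 2 ** (self.levels - 1) != 0:
            raise ValueError(
                f"roi edge {self.roi_edge_mm} not divisible through {self.levels} levels"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.kernel_edge != 3:
            raise ValueError("only 3x3x3 kernels are supported")

    @property
    def name(self) -> str:
        return f"CropNet-b{self.blocks_per_level}-{self.roi_edge_mm}mm"

    @classmethod
    def b2_16mm(cls, widths: tuple[int, ...] = DEFAULT_WIDTHS) -> "ModelSpec":
        return cls(blocks_per_level=2, roi_edge_mm=16, widths=widths)

    @classmethod
    def b4_16mm(cls, widths: tuple[int, ...] = DEFAULT_WIDTHS) -> "ModelSpec":
        return cls(blocks_per_level=4, roi_edge_mm=16, widths=widths)


class Classifier:
    """A CropNet parameter set theta with forward map ROI -> [0, 1]."""

    def __init__(self, spec: ModelSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        layers: list = []
        cin = 1
        for level in range(spec.levels):
            cout = spec.widths[level]
            for _ in range(spec.blocks_per_level):
                layers.append(eng.Conv3D(cin, cout, rng, first=not layers))
                layers.append(eng.ReLU())
                layers.append(eng.Dropout(spec.dropout_rate))
                cin = cout
            if level < spec.levels - 1:
                layers.append(eng.MaxPool2())
        final_edge = spec.roi_edge_mm // 2 ** (spec.levels - 1)
        layers.append(eng.DenseHead(final_edge**3 * cin, rng))
        self.net = eng.Sequential(layers)

    # ------------------------------------------------------------------
    def _prepare(self, rois: np.ndarray) -> np.ndarray:
        rois = np.asarray(rois, dtype=np.float32)
        if rois.ndim == 3:
            rois = rois[None]
        if rois.ndim == 4:
            rois = rois[..., None]
        e = self.spec.roi_edge_mm
        if rois.shape[1:] != (e, e, e, 1):
            raise DimensionError(
                f"{self.spec.name} expects ({e},{e},{e}) ROIs, got {rois.shape[1:]}"
            )
        return rois

    def forward_logits(self, rois: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Pre-sigmoid responses.  ``train=True`` activates dropout (model noise)
        and caches activations for :meth:`backward`."""
        x = self._prepare(rois)
        if train:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            self.net.set_dropout_rng(rng)
        return self.net.forward(x, train=train)

    def forward(self, rois: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Deterministic inference responses in [0, 1], batched for memory."""
        x = self._prepare(rois)
        out = np.empty(len(x), dtype=np.float32)
        for i in range(0, len(x), batch_size):
            z = self.net.forward(x[i : i + batch_size], train=False)
            out[i : i + batch_size] = _sigmoid(z)
        return out

    def backward(self, glogits: np.ndarray) -> None:
        self.net.backward(glogits)

    # ------------------------------------------------------------------
    def count_parameters(self) -> int:
        return self.net.n_params()

    def save(self, path) -> None:
        """Checkpoint: spec (JSON) + parameter arrays + init seed, one .npz file."""
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params)}
        np.savez(
            path,
            spec=np.frombuffer(json.dumps(asdict(self.spec)).encode(), dtype=np.uint8),
            seed=np.int64(self.seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Classifier":
        with np.load(path) as data:
            spec_dict = json.loads(bytes(data["spec"].tobytes()).decode())
            spec_dict["widths"] = tuple(spec_dict["widths"])
            model = cls(ModelSpec(**spec_dict), int(data["seed"]))
            for i, p in enumerate(model.net.params):
                p[...] = data[f"p{i}"]
        return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(spec: ModelSpec, seed: int) -> Classifier:
    """Instantiate a classifier with fan-in-scaled random init from ``seed``."""
    return Classifier(spec, seed)


def count_parameters(model: Classifier) -> int:
    """Total trainable scalar parameters (weights + biases)."""
    return model.count_parameters()
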