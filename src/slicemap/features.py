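"""Per-slice feature vectors through a frozen 2D convolutional backbone.

Each 224 x 224 x 3 slice passes through a truncated convolutional stack
(classification layers removed), global average pooling, and a fixed
20-unit linear projection; stacking the per-slice vectors over the 200
slices of a slab yields the subject's 200 x 20 feature map. The whole
extractor is frozen — it is a pure, seeded function of its spec — so a
feature map is fully determined by (backbone spec, slab).

Two weight sources exist behind one contract:

* ``random`` — a small seeded convolutional stack (bias-free, ReLU,
  strided + pooled). Random convolutional features preserve coarse
  spatial intensity structure, which is all the desk-scale phantom
  studies need, and nothing has to be downloaded.
* ``pretrained`` — a conv stack loaded from a local ``.npz`` weights file
  (keys ``conv{i}_W`` shaped (C_in, k, k, C_out), optional ``conv{i}_b``,
  and ``pool_after`` listing conv indices followed by 2x2 max pooling).
  This is how ImageNet-style weights, exported once, are consumed; no
  test ever requires such a file.

Feature maps serialise as a TSV matrix plus a JSON sidecar carrying the
subject id, shape, backbone fingerprint and creation parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import conv2d_forward, glorot
from .volume import SlabStack, TARGET_SIZE

__all__ = ["BackboneSpec", "FeatureMap", "Extractor", "build_extractor",
           "extract_slice_features", "build_feature_map",
           "save_feature_map", "load_feature_map"]


@dataclass(frozen=True)
class BackboneSpec:
    """Configuration of the frozen extractor.

    ``projection_dim`` defaults to the 20 features retained per slice;
    ``projection_seed`` fixes both the projection and (in random mode)
    the convolutional weights.
    """

    weights_source: str = "random"
    weights_path: str | None = None
    truncation_point: str = "last_conv"
    projection_dim: int = 20
    projection_seed: int = 0

    def __post_init__(self):
        if self.weights_source not in ("random", "pretrained"):
            raise ValueError(f"weights_source must be 'random' or 'pretrained', "
                             f"got {self.weights_source!r}")
        if self.projection_dim < 1:
            raise ValueError(f"projection_dim must be >= 1, got {self.projection_dim}")


@dataclass
class FeatureMap:
    """Per-subject matrix of shape (n_slices, projection_dim)."""

    matrix: np.ndarray
    subject_id: str = ""
    backbone_fingerprint: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"feature map must be 2D, got shape {self.matrix.shape}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature map contains non-finite entries")


class Extractor:
    """Frozen slice-to-vector map: conv stack -> GAP -> linear projection."""

    def __init__(self, convs, pool_after, projection, spec: BackboneSpec):
        self.convs = convs            # list of (W, b|None, stride)
        self.pool_after = set(pool_after)
        self.projection = projection  # (C_last, projection_dim)
        self.spec = spec
        self.fingerprint = self._fingerprint()

    def _fingerprint(self) -> str:
        h = hashlib.sha256()
        for W, b, stride in self.convs:
            h.update(np.ascontiguousarray(W))
            if b is not None:
                h.update(np.ascontiguousarray(b))
            h.update(str(stride).encode())
        h.update(np.ascontiguousarray(self.projection))
        return h.hexdigest()[:16]

    # -- forward ----------------------------------------------------------

    def _check(self, slice3: np.ndarray) -> np.ndarray:
        slice3 = np.asarray(slice3, dtype=np.float64)
        if slice3.shape != (TARGET_SIZE, TARGET_SIZE, 3):
            raise ValueError(f"expected a ({TARGET_SIZE}, {TARGET_SIZE}, 3) slice, "
                             f"got shape {slice3.shape}")
        return slice3

    def last_conv_activation(self, slice3: np.ndarray) -> np.ndarray:
        """Post-ReLU activation of the final convolution, as (H, W, C)."""
        x = self._check(slice3).transpose(2, 0, 1)[None]  # (1, 3, H, W)
        for idx, (W, b, stride) in enumerate(self.convs):
            x, _ = conv2d_forward(x, W, b, stride)
            np.maximum(x, 0.0, out=x)
            if idx in self.pool_after and idx < len(self.convs) - 1:
                x = _maxpool2(x)
        return x[0].transpose(1, 2, 0)

    def extract(self, slice3: np.ndarray) -> np.ndarray:
        act = self.last_conv_activation(slice3).transpose(2, 0, 1)[None]
        if len(self.convs) - 1 in self.pool_after:
            act = _maxpool2(act)
        pooled = act.mean(axis=(2, 3))[0]          # global average pooling
        return pooled @ self.projection


def _maxpool2(x: np.ndarray) -> np.ndarray:
    N, C, H, W = x.shape
    return x[:, :, :H // 2 * 2, :W // 2 * 2].reshape(N, C, H // 2, 2, W // 2, 2).max(axis=(3, 5))


def build_extractor(spec: BackboneSpec) -> Extractor:
    """Instantiate the frozen extractor for a spec.

    ``pretrained`` requires ``weights_path`` to exist; the error suggests
    random mode, which needs no file.
    """
    rng = np.random.default_rng(np.random.SeedSequence([20, spec.projection_seed]))
    if spec.weights_source == "random":
        # bias-free so an all-zero slice yields an exactly-zero activation
        convs = [
            (glorot(rng, (3, 3, 3, 8), 27, 72), None, 2),
            (glorot(rng, (8, 3, 3, 16), 72, 144), None, 2),
        ]
        pool_after = {0, 1}
        c_last = 16
    else:
        path = spec.weights_path
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                f"pretrained backbone weights not found at {path!r}; export the conv "
                "weights to an .npz first, or use weights_source='random' (no file needed)")
        with np.load(path) as npz:
            idxs = sorted(int(k[4:].split("_")[0]) for k in npz.files if k.endswith("_W"))
            convs = [(npz[f"conv{i}_W"].astype(np.float64),
                      npz[f"conv{i}_b"].astype(np.float64) if f"conv{i}_b" in npz.files else None,
                      1) for i in idxs]
            pool_after = set(int(i) for i in npz["pool_after"]) if "pool_after" in npz.files else set()
        c_last = convs[-1][0].shape[3]
    projection = glorot(rng, (c_last, spec.projection_dim), c_last, spec.projection_dim)
    return Extractor(convs, pool_after, projection, spec)


def extract_slice_features(extractor: Extractor, slice3: np.ndarray) -> np.ndarray:
    """Feature vector (length ``projection_dim``) for one slice."""
    return extractor.extract(slice3)


def build_feature_map(extractor: Extractor, stack: SlabStack) -> FeatureMap:
    """Row i of the matrix is the feature vector of slice i, in slice order.

    All-zero (blank-padded) slices share one computed vector, so their
    rows are bit-identical — the visible trace of the padding scheme.
    """
    n = stack.n_slices
    mat = np.empty((n, extractor.spec.projection_dim))
    zero_vec = None
    for i in range(n):
        sl = stack.data[i]
        try:
            if not sl.any():
                if zero_vec is None:
                    zero_vec = extractor.extract(sl)
                mat[i] = zero_vec
            else:
                mat[i] = extractor.extract(sl)
        except ValueError as exc:
            raise ValueError(f"slice {i}: {exc}") from exc
    return FeatureMap(matrix=mat, subject_id=stack.source_id,
                      backbone_fingerprint=extractor.fingerprint)


def save_feature_map(fmap: FeatureMap, path: str | Path) -> None:
    """Write the matrix as TSV plus a JSON sidecar (lossless round trip)."""
    path = Path(path)
    np.savetxt(path, fmap.matrix, delimiter="\t", fmt="%.17g")
    sidecar = dict(subject_id=fmap.subject_id, shape=list(fmap.matrix.shape),
                   backbone_fingerprint=fmap.backbone_fingerprint)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def load_feature_map(path: str | Path, expected_fingerprint: str | None = None) -> FeatureMap:
    """Load a TSV + sidecar pair; sidecar/TSV disagreement is an error."""
    import logging
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar file {side} for feature map {path}")
    meta = json.loads(side.read_text())
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    if list(mat.shape) != list(meta["shape"]):
        raise ValueError(f"sidecar shape {meta['shape']} disagrees with TSV shape {list(mat.shape)}")
    fp = meta.get("backbone_fingerprint", "")
    if expected_fingerprint is not None and fp != expected_fingerprint:
        logging.getLogger(__name__).warning(
            "feature map %s was built with backbone %s, expected %s", path, fp, expected_fingerprint)
    return FeatureMap(matrix=mat, subject_id=meta.get("subject_id", ""), backbone_fingerprint=fp)
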