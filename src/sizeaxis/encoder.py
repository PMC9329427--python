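"""A layered random-filter visual encoder with channel-mean extraction.

The encoder is a stack of convolution + rectification + mean-pool stages
with randomly drawn, zero-DC filter banks.  Responses are read out at a
configurable split layer as **pre-rectification spatial channel means** —
one number per channel per stimulus — which is the representation all the
object-space analyses operate on.  Untrained random filter banks double as
the null model for permutation-style significance testing: a freshly seeded
encoder is a generic visual front end with no learned object knowledge.

A frozen linear readout (multinomial logistic regression on channel means)
stands in for downstream classification layers in the ablation analysis:
variance is removed from the channel means, and the *unchanged* readout is
re-evaluated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, rotate
from sklearn.linear_model import LogisticRegression

from ._utils import rng_from
from .errors import (DimensionError, FrozenReadoutError, ParameterError,
                     UnfitReadoutError)


@dataclass
class ResponseMatrix:
    """Stimuli x channels activation matrix with aligned stimulus ids."""

    values: np.ndarray
    stimulus_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("values must be 2-D (stimuli x channels)")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("response matrix contains non-finite entries")
        if not self.stimulus_ids:
            self.stimulus_ids = [f"stim{i:04d}" for i in range(len(self.values))]
        if len(self.stimulus_ids) != self.values.shape[0]:
            raise DimensionError("stimulus_ids not aligned with values")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def channel_count(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values,
                          columns=[f"ch{i:03d}" for i in range(self.channel_count)])
        df.insert(0, "id", self.stimulus_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        """Adapter entry point: any tool producing a stimuli x channels CSV
        with an ``id`` column is accepted."""
        df = pd.read_csv(path)
        ids = df["id"].astype(str).tolist()
        return cls(values=df.drop(columns=["id"]).to_numpy(dtype=float),
                   stimulus_ids=ids)


@dataclass
class EncoderModel:
    """A random-filter convolutional stack with an optional frozen readout."""

    filters: list[np.ndarray]   # per layer: (C_out, C_in, k, k)
    split_layer: int            # 1-based layer whose channel means are read out
    image_px: int
    seed: int
    readout: LogisticRegression | None = None

    @property
    def n_layers(self) -> int:
        return len(self.filters)

    @property
    def channel_count(self) -> int:
        return self.filters[self.split_layer - 1].shape[0]

    def spec_dict(self) -> dict:
        return dict(n_layers=self.n_layers,
                    channels_per_layer=[w.shape[0] for w in self.filters],
                    kernel_px=self.filters[0].shape[-1],
                    split_layer=self.split_layer,
                    image_px=self.image_px, seed=self.seed)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.spec_dict()))


def build_encoder(n_layers: int = 2, channels_per_layer=(16, 32),
                  image_px: int = 64, seed: int = 0, kernel_px: int = 5,
                  split_layer: int | None = None) -> EncoderModel:
    """Instantiate a deterministic random-filter encoder.

    Filters are zero-mean (no DC response) and unit-norm, with a per-filter
    random smoothing scale so the bank spans a range of spatial-frequency
    tunings.  No training is involved; two builds with the same seed produce
    identical responses.
    """
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    channels_per_layer = list(channels_per_layer)
    if len(channels_per_layer) != n_layers:
        raise ParameterError("channels_per_layer length must equal n_layers")
    if split_layer is None:
        split_layer = n_layers
    if not (1 <= split_layer <= n_layers):
        raise ParameterError("split_layer out of range")

    rng = rng_from(seed, "encoder")
    filters = []
    c_in = 1
    for c_out in channels_per_layer:
        w = rng.standard_normal((c_out, c_in, kernel_px, kernel_px))
        for i in range(c_out):
            # anisotropic smoothing at a random orientation gives each filter
            # a random spatial-scale and orientation tuning (V1-like bank)
            s_short = rng.uniform(0.2, 1.0)
            s_long = s_short * rng.uniform(1.0, 3.0)
            ang = rng.uniform(0.0, 180.0)
            sm = gaussian_filter(w[i], sigma=(0, s_short, s_long))
            w[i] = rotate(sm, ang, axes=(1, 2), reshape=False, order=1,
                          mode="nearest")
            w[i] -= w[i].mean()
            w[i] /= np.linalg.norm(w[i]) + 1e-12
        filters.append(w)
        c_in = c_out
    return EncoderModel(filters=filters, split_layer=split_layer,
                        image_px=image_px, seed=seed)


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid-mode convolution of (n, C_in, H, W) with (C_out, C_in, k, k)."""
    k = w.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (n, C_in, H', W', k, k)
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
    return np.moveaxis(out, 3, 1)


def _mean_pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))


def encode(model: EncoderModel, stimuli) -> ResponseMatrix:
    """Channel-averaged responses at the split layer, before rectification.

    ``stimuli`` may be a :class:`~sizeaxis.synthetic.SizeRankedStimuli` or a
    raw (n, H, W) image stack matching the encoder's resolution.
    """
    if hasattr(stimuli, "images"):
        images = np.asarray(stimuli.images, dtype=np.float32)
        ids = stimuli.ids
    else:
        images = np.asarray(stimuli, dtype=np.float32)
        ids = []
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1] != model.image_px or images.shape[2] != model.image_px:
        raise DimensionError(
            f"images must be (n, {model.image_px}, {model.image_px}); got {images.shape}")

    x = images[:, None, :, :]
    for layer in range(1, model.n_layers + 1):
        z = _conv_valid(x, model.filters[layer - 1].astype(np.float32))
        if layer == model.split_layer:
            means = z.mean(axis=(2, 3)).astype(float)  # pre-rectification
            return ResponseMatrix(values=means, stimulus_ids=ids)
        x = _mean_pool2(np.maximum(z, 0.0))
    raise AssertionError("unreachable: split_layer validated at build time")


def fit_readout(model: EncoderModel, responses: ResponseMatrix, labels) -> EncoderModel:
    """Fit a multinomial linear readout on channel means and freeze it.

    Returns a copy of the model carrying the fitted readout; the readout is
    immutable thereafter, so ablation runs evaluate a genuinely frozen
    downstream stage.
    """
    if model.readout is not None:
        raise FrozenReadoutError("readout already fitted and frozen")
    labels = np.asarray(labels)
    if len(labels) != responses.n_stimuli:
        raise DimensionError("labels not aligned with responses")
    if len(np.unique(labels)) < 2:
        raise ParameterError("need at least 2 classes to fit a readout")
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(responses.values, labels)
    return dataclasses.replace(model, readout=clf)


def readout_accuracy(model: EncoderModel, responses: ResponseMatrix, labels) -> float:
    """Top-1 accuracy of the frozen readout on the given responses."""
    if model.readout is None:
        raise UnfitReadoutError("readout has not been fitted")
    labels = np.asarray(labels)
    pred = model.readout.predict(responses.values)
    return float(np.mean(pred == labels))
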