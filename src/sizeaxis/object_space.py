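"""PCA object space: axis extraction, per-axis variance removal, dropout
statistics, and the recognition-ablation analysis.

The object space is built by PCA on channel-mean responses after each
channel is divided by its L2 norm across stimuli and mean-centered; axes are
retained up to a cumulative explained-variance threshold (default 90%).
Whether a retained axis *specifically* carries the size feature is measured
by the dropout index

    DI_i = z(R) - z(r_i),

the Fisher-z drop in ideal-observer correspondence when axis i's variance is
regressed out of the responses.  Significance comes from an empirical null:
the identical procedure repeated on freshly seeded *untrained* encoders
viewing the same stimuli, with the null DIs of all axes pooled into one
distribution and Bonferroni correction over the retained axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed, rng_from
from .encoder import (EncoderModel, ResponseMatrix, build_encoder, encode,
                      readout_accuracy)
from .errors import (DimensionError, NormalizationError, ParameterError,
                     UndefinedStatisticError)
from .rsa import ideal_observer_rsm, rank_rsm, rsm_correspondence

#: default configuration of the untrained null encoders used by the
#: permutation-style significance procedures (compact at desk scale; channel
#: count is overridden where it must match the data)
DEFAULT_NULL_ENCODER = dict(n_layers=2, channels_per_layer=(8, 16), kernel_px=5)


@dataclass
class ObjectSpace:
    """Orthonormal PCA axes over channels, with the normalization record."""

    axes: np.ndarray             # channels x n_retained, orthonormal columns
    explained_ratio: np.ndarray  # per retained axis, nonincreasing
    var_threshold: float
    normalizer: np.ndarray       # per-channel L2 norm across stimuli
    center: np.ndarray           # per-channel mean after normalization

    @property
    def n_retained(self) -> int:
        return self.axes.shape[1]

    @property
    def channel_count(self) -> int:
        return self.axes.shape[0]

    def save(self, axes_csv, meta_json) -> None:
        pd.DataFrame(self.axes,
                     columns=[f"pc{i+1}" for i in range(self.n_retained)]).to_csv(
            axes_csv, index=False)
        Path(meta_json).write_text(json.dumps(dict(
            var_threshold=self.var_threshold,
            explained_ratio=self.explained_ratio.tolist(),
            normalizer=self.normalizer.tolist(),
            center=self.center.tolist())))


@dataclass
class ComponentScores:
    """Projections of stimuli onto the retained axes (stimuli x n_retained)."""

    values: np.ndarray

    def axis(self, i: int) -> np.ndarray:
        """Scores on axis ``i`` (1-based: ``axis(2)`` is PC2)."""
        return self.values[:, i - 1]


@dataclass
class DropoutResult:
    """Per-axis dropout indices with pooled-null significance."""

    di: np.ndarray
    reference_r: float
    removed_r: np.ndarray
    null_samples: np.ndarray
    p_corrected: np.ndarray
    alpha: float
    significant: np.ndarray
    resolution_warning: bool = False

    @property
    def n_retained(self) -> int:
        return len(self.di)

    def significant_axes(self) -> list[int]:
        """1-based indices of significant axes."""
        return [int(i) + 1 for i in np.nonzero(self.significant)[0]]

    def save(self, json_path, null_csv=None) -> None:
        rec = dict(di=self.di.tolist(), reference_r=self.reference_r,
                   removed_r=self.removed_r.tolist(),
                   p_corrected=self.p_corrected.tolist(), alpha=self.alpha,
                   significant=[bool(s) for s in self.significant],
                   resolution_warning=self.resolution_warning,
                   null_summary=dict(n=int(len(self.null_samples)),
                                     q95=float(np.quantile(self.null_samples, 0.95)),
                                     q99=float(np.quantile(self.null_samples, 0.99))))
        Path(json_path).write_text(json.dumps(rec))
        if null_csv is not None:
            pd.DataFrame({"null_di": self.null_samples}).to_csv(null_csv, index=False)


def _normalize(responses: ResponseMatrix, normalizer=None, center=None):
    X = responses.values
    if normalizer is None:
        normalizer = np.linalg.norm(X, axis=0)
        zero = np.nonzero(normalizer == 0)[0]
        if zero.size:
            raise NormalizationError(f"channel {zero[0]} has zero norm across stimuli")
    Xn = X / normalizer
    if center is None:
        center = Xn.mean(axis=0)
    return Xn - center, normalizer, center


def build_object_space(responses: ResponseMatrix, var_threshold: float = 0.9
                       ) -> tuple[ObjectSpace, ComponentScores]:
    """PCA on L2-normalized, mean-centered channel responses.

    Retains the smallest number of leading axes whose cumulative explained
    variance reaches ``var_threshold``.  Axis signs are fixed so each axis's
    largest-magnitude channel loading is positive.
    """
    if responses.n_stimuli < 2 or responses.channel_count < 2:
        raise DimensionError("need at least 2 stimuli and 2 channels")
    if not (0 < var_threshold <= 1):
        raise ParameterError("var_threshold must be in (0, 1]")
    Xc, normalizer, center = _normalize(responses)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ratios = s ** 2 / np.sum(s ** 2)
    n_retained = int(np.searchsorted(np.cumsum(ratios), var_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(ratios))
    axes = vt[:n_retained].T.copy()
    for i in range(n_retained):
        j = int(np.argmax(np.abs(axes[:, i])))
        if axes[j, i] < 0:
            axes[:, i] = -axes[:, i]
    space = ObjectSpace(axes=axes, explained_ratio=ratios[:n_retained].copy(),
                        var_threshold=var_threshold, normalizer=normalizer,
                        center=center)
    return space, ComponentScores(values=Xc @ axes)


def project(space: ObjectSpace, responses: ResponseMatrix) -> ComponentScores:
    """Project new stimuli into a frozen object space (same normalizer)."""
    if responses.channel_count != space.channel_count:
        raise DimensionError("channel count does not match the object space")
    Xc, _, _ = _normalize(responses, space.normalizer, space.center)
    return ComponentScores(values=Xc @ space.axes)


def remove_axis_variance(responses: ResponseMatrix, space: ObjectSpace,
                         axis: int) -> ResponseMatrix:
    """Regress one retained axis's variance out of the responses.

    ``axis`` is 1-based (``axis=2`` removes PC2).  The residual is computed
    in normalized space and mapped back through the normalizer, so downstream
    consumers see the original response scale.
    """
    if not (1 <= axis <= space.n_retained):
        raise IndexError(f"axis {axis} outside retained range 1..{space.n_retained}")
    return remove_direction_variance(responses, space, space.axes[:, axis - 1])


def remove_direction_variance(responses: ResponseMatrix, space: ObjectSpace,
                              direction: np.ndarray) -> ResponseMatrix:
    """Regress out an arbitrary unit direction in normalized channel space."""
    v = np.asarray(direction, dtype=float)
    if v.shape != (space.channel_count,):
        raise DimensionError("direction must be a channel-space vector")
    v = v / np.linalg.norm(v)
    Xc, _, _ = _normalize(responses, space.normalizer, space.center)
    resid = Xc - np.outer(Xc @ v, v)
    back = (resid + space.center) * space.normalizer
    return ResponseMatrix(values=back, stimulus_ids=list(responses.stimulus_ids))


def _fisher_z(r: float) -> float:
    if abs(r) >= 1.0:
        raise UndefinedStatisticError(
            "|r| = 1: Fisher z is infinite — add jitter to the responses")
    return float(np.arctanh(r))


def dropout_index(responses: ResponseMatrix, space: ObjectSpace, axis: int,
                  ranks) -> float:
    """DI = z(R) - z(r_axis) for one retained axis (1-based)."""
    n_ranks = int(np.max(ranks))
    ideal = ideal_observer_rsm(n_ranks)
    R = rsm_correspondence(rank_rsm(responses, ranks), ideal)
    resid = remove_axis_variance(responses, space, axis)
    r_axis = rsm_correspondence(rank_rsm(resid, ranks), ideal)
    return _fisher_z(R) - _fisher_z(r_axis)


def _all_axis_dis(responses: ResponseMatrix, space: ObjectSpace, ranks, ideal):
    """Reference correspondence R and the DI of every retained axis.

    Algebraically identical to calling :func:`dropout_index` per axis, but
    the rank means of each residual are formed directly — axis removal is
    linear, so it commutes with rank averaging — which makes the thousands
    of evaluations inside a permutation null affordable.
    """
    ranks = np.asarray(ranks, dtype=int)
    n_ranks = ideal.n_ranks
    X = responses.values
    # rank-averaging operator G: (K x n), rows sum to 1
    G = np.zeros((n_ranks, X.shape[0]))
    for r in range(1, n_ranks + 1):
        sel = ranks == r
        if not sel.any():
            from .errors import BinningError
            raise BinningError(f"rank {r} has zero members")
        G[r - 1, sel] = 1.0 / sel.sum()
    M = G @ X                                   # rank means, original scale
    Xc, _, _ = _normalize(responses, space.normalizer, space.center)
    scores = Xc @ space.axes                    # (n x k)
    Ms = G @ scores                             # rank means of axis scores
    iu = np.triu_indices(n_ranks, k=1)
    ideal_ut = ideal.values[iu]

    def _corr(Mat):
        v = np.corrcoef(Mat)[iu]
        if np.ptp(v) == 0 or np.any(~np.isfinite(v)):
            raise UndefinedStatisticError("degenerate rank-mean RSM")
        return float(np.corrcoef(v, ideal_ut)[0, 1])

    R = _corr(M)
    zR = _fisher_z(R)
    dis = np.empty(space.n_retained)
    removed = np.empty(space.n_retained)
    for i in range(space.n_retained):
        M_res = M - np.outer(Ms[:, i], space.axes[:, i] * space.normalizer)
        removed[i] = _corr(M_res)
        dis[i] = zR - _fisher_z(removed[i])
    return R, dis, removed


def dropout_significance(responses: ResponseMatrix, ranks, stimuli=None,
                         null_responses_fn=None, var_threshold: float = 0.9,
                         n_null_reps: int = 200, alpha: float = 0.05,
                         seed: int = 0, null_encoder: dict | None = None,
                         permute_null_ranks: bool = True) -> DropoutResult:
    """Dropout indices for every retained axis, with pooled-null p-values.

    The null repeats the full build-space / drop-axis / re-correlate
    procedure on responses from freshly seeded untrained encoders shown the
    same stimuli (the generic-front-end null), pooling the DIs of *all*
    retained axes of every null space into one distribution.  Per-axis
    p-values are upper-tail empirical probabilities with the add-one
    convention; Bonferroni correction divides ``alpha`` by the number of
    retained axes.

    With ``permute_null_ranks=True`` (default) the size-rank labels are
    freshly permuted inside every null repetition, so the null distribution
    describes a generic encoder with **no size-aligned axis** — the premise
    an untrained-network null is meant to embody.  Without it, whatever
    size information a random filter bank happens to extract from the
    stimuli themselves remains in the null, which makes the test
    conservative on stimuli whose size cues are visible to generic filters.

    Either ``stimuli`` (images for the default encoder null) or a callable
    ``null_responses_fn(rep_seed) -> ResponseMatrix`` must be provided.
    """
    if n_null_reps < 100:
        raise ParameterError("n_null_reps must be >= 100")
    ranks = np.asarray(ranks, dtype=int)
    n_ranks = int(ranks.max())
    ideal = ideal_observer_rsm(n_ranks)

    space, _ = build_object_space(responses, var_threshold)
    R, dis, removed = _all_axis_dis(responses, space, ranks, ideal)

    if null_responses_fn is None:
        if stimuli is None:
            raise ParameterError("provide stimuli or null_responses_fn for the null")
        cfg = dict(DEFAULT_NULL_ENCODER if null_encoder is None else null_encoder)
        image_px = np.asarray(stimuli.images).shape[-1]

        def null_responses_fn(rep_seed):
            enc = build_encoder(image_px=image_px, seed=rep_seed, **cfg)
            return encode(enc, stimuli)

    perm_rng = rng_from(seed, "null-rank-perm")
    null_dis = []
    for rep in range(n_null_reps):
        resp0 = null_responses_fn(child_seed(seed, "null", rep))
        space0, _ = build_object_space(resp0, var_threshold)
        null_ranks = perm_rng.permutation(ranks) if permute_null_ranks else ranks
        _, dis0, _ = _all_axis_dis(resp0, space0, null_ranks, ideal)
        null_dis.append(dis0)
    pool = np.concatenate(null_dis)

    m = len(pool)
    p = (np.sum(pool[None, :] >= dis[:, None], axis=1) + 1.0) / (m + 1.0)
    threshold = alpha / space.n_retained
    return DropoutResult(di=dis, reference_r=R, removed_r=removed,
                         null_samples=pool, p_corrected=p, alpha=alpha,
                         significant=p <= threshold,
                         resolution_warning=threshold < 1.0 / (m + 1.0))


@dataclass
class AblationResult:
    """Recognition-accuracy impact of removing one axis's variance."""

    acc_full: float
    acc_ablated: float
    p: float
    null_drops: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def drop(self) -> float:
        return self.acc_full - self.acc_ablated


def ablate_recognition(model: EncoderModel, space: ObjectSpace, axis: int,
                       responses: ResponseMatrix, labels, stimuli=None,
                       null_responses_fn=None, n_null_reps: int = 200,
                       seed: int = 0, null_encoder: dict | None = None
                       ) -> AblationResult:
    """Top-1 accuracy of the frozen readout before vs. after axis removal.

    The null distribution of accuracy drops comes from *baseline* object
    spaces: untrained encoders are shown the same stimuli, their retained
    axes are regressed out of the **original** responses, and the frozen
    readout is re-evaluated — drops from all baseline axes are pooled.  The
    one-sided p-value is the pooled fraction of null drops at least as large
    as the observed one (add-one convention).
    """
    acc_full = readout_accuracy(model, responses, labels)
    ablated = remove_axis_variance(responses, space, axis)
    acc_abl = readout_accuracy(model, ablated, labels)
    obs_drop = acc_full - acc_abl

    if null_responses_fn is None:
        if stimuli is None:
            raise ParameterError("provide stimuli or null_responses_fn for the null")
        cfg = dict(DEFAULT_NULL_ENCODER if null_encoder is None else null_encoder)
        # baseline axes must live in the data's channel space
        cfg["channels_per_layer"] = (*cfg["channels_per_layer"][:-1],
                                     responses.channel_count)
        image_px = np.asarray(stimuli.images).shape[-1]

        def null_responses_fn(rep_seed):
            enc = build_encoder(image_px=image_px, seed=rep_seed, **cfg)
            return encode(enc, stimuli)

    drops = []
    for rep in range(n_null_reps):
        resp0 = null_responses_fn(child_seed(seed, "abl-null", rep))
        space0, _ = build_object_space(resp0, space.var_threshold)
        for i in range(space0.n_retained):
            resid = remove_direction_variance(responses, space, space0.axes[:, i])
            drops.append(acc_full - readout_accuracy(model, resid, labels))
    drops = np.asarray(drops)
    p = (np.sum(drops >= obs_drop) + 1.0) / (len(drops) + 1.0)
    return AblationResult(acc_full=acc_full, acc_ablated=acc_abl, p=float(p),
                          null_drops=drops)


def orient_axis_to_log_size(scores: ComponentScores, axis: int, sizes_cm,
                            space: ObjectSpace | None = None) -> np.ndarray:
    """Return axis scores with the sign chosen so the correlation with
    log10(size) is nonnegative (reporting stability convention).  When a
    space is given, its stored axis is flipped in place to match."""
    s = scores.axis(axis).copy()
    r = np.corrcoef(s, np.log10(np.asarray(sizes_cm, dtype=float)))[0, 1]
    if r < 0:
        s = -s
        scores.values[:, axis - 1] = s
        if space is not None:
            space.axes[:, axis - 1] = -space.axes[:, axis - 1]
    return s
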