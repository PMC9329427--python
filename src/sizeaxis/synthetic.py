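"""Synthetic stimuli, activations, and size judgments with known ground truth.

The generator emulates the statistical structure that the size-axis analyses
assume about real object photographs, while keeping every nuisance dimension
under explicit control:

* **Real-world sizes** are sampled log-uniformly (uniform in ``log10``) over a
  configurable range spanning centimeters to tens of meters — the simplest
  heavy-tailed model of everyday object sizes — stratified so that every one
  of the ``K`` log-spaced size ranks receives exactly ``n_per_rank`` objects.
* **Retinal size is decoupled from real-world size**: in the default
  ``"fixed"`` mode every object is drawn with the same bounding-box diagonal,
  so nothing about how much of the image an object covers carries size
  information.
* **Shape carries size** through the *orientation* of an elongated object:
  the long axis rotates from vertical to horizontal as ``log10`` size runs
  over its range.  Orientation is a global shape property that survives
  silhouetting, is destroyed by a pixel shuffle, and — being a rigid
  rotation — leaves the aspect-ratio curvature statistic exactly unchanged,
  so curvature stays decorrelated from size by construction.  Base shapes
  (ellipse, rounded rectangle, convex polygon, star — all deformed
  ellipses, so the bounding-box diagonal is rotation-stable) and their
  elongations are drawn independently of size.
* **Texture carries size** through the wavelength of an interior grating of
  fixed contrast; the pixel histogram is therefore (to raster precision)
  independent of size, so a global pixel shuffle destroys the cue.

``generate_planted_activations`` bypasses images entirely and plants a known
latent axis whose scores follow ``beta * g(size) + noise`` inside an otherwise
isotropic latent model — the ground truth for parameter-recovery tests of the
object-space machinery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from skimage.draw import polygon as draw_polygon

from ._utils import child_seed, rng_from
from .errors import DimensionError, ParameterError

MAPPING_FAMILIES = ("linear", "pow033", "pow05", "pow2", "pow3", "log10")

_SHAPE_FAMILIES = ("ellipse", "rectangle", "polygon", "star")

# Default study conditions: orientation sweep of the long axis (radians) and
# its jitter; elongation range of the base shapes; texture grating wavelength
# range in pixels.  Chosen to give an untrained filter-bank encoder a clear
# but imperfect (mid-level-layer-like) view of object size.
_ORIENT_SWEEP = np.pi / 2
_ORIENT_JITTER = 0.07
_ELONGATION = (0.40, 0.85)
_TEXTURE_WAVELEN_PX = (4.0, 12.0)
_TEXTURE_BASE = (0.15, 0.40)   # per-stimulus interior gray, size-independent
_TEXTURE_AMP = (0.08, 0.18)    # per-stimulus grating contrast, size-independent
_TEXTURE_ORI_JITTER = 0.60
_DIAG_JITTER = 0.02            # relative bounding-diagonal jitter (both modes)


@dataclass
class SizeRankedStimuli:
    """A set of grayscale object images with known real-world sizes.

    Per-stimulus arrays are index-aligned. ``images`` holds intensities in
    [0, 1] with a white (1.0) background; ``ranks`` are 1-based size ranks.
    """

    images: np.ndarray          # (n, H, W) float64 in [0, 1]
    sizes_cm: np.ndarray        # (n,) positive
    ranks: np.ndarray           # (n,) int in 1..n_ranks
    category: np.ndarray        # (n,) int labels
    animate: np.ndarray         # (n,) bool
    retinal_diag_px: np.ndarray # (n,) positive
    n_ranks: int
    size_range_cm: tuple[float, float]

    def __post_init__(self):
        n = len(self.sizes_cm)
        for name in ("images", "ranks", "category", "animate", "retinal_diag_px"):
            if len(getattr(self, name)) != n:
                raise DimensionError(f"field {name!r} not aligned with sizes_cm")
        if np.any(np.asarray(self.sizes_cm) <= 0):
            raise ParameterError("sizes_cm must be positive")

    def __len__(self) -> int:
        return len(self.sizes_cm)

    @property
    def ids(self) -> list[str]:
        return [f"stim{i:04d}" for i in range(len(self))]

    def rank_counts(self) -> np.ndarray:
        return np.bincount(self.ranks, minlength=self.n_ranks + 1)[1:]


@dataclass
class PlantedGroundTruth:
    """Ground truth for activations with a planted size axis.

    ``loadings`` maps ``n_latent`` latent scores into channel space; the
    column ``planted_axis_index`` (1-based) carries ``beta * g(size)`` with
    ``g`` given by ``mapping_family``; the remaining latent scores are
    independent standard normal. ``noise_sd`` is used both for the jitter on
    the planted score and for the isotropic channel noise.
    """

    loadings: np.ndarray
    planted_axis_index: int = 2
    beta: float = 1.4
    noise_sd: float = 0.25
    mapping_family: str = "log10"

    def __post_init__(self):
        L = np.asarray(self.loadings, dtype=float)
        if L.ndim != 2:
            raise DimensionError("loadings must be a channels x n_latent matrix")
        gram = L.T @ L
        if not np.allclose(gram, np.eye(L.shape[1]), atol=1e-8):
            raise ParameterError("loadings columns must be orthonormal to 1e-8")
        if not (1 <= self.planted_axis_index <= L.shape[1]):
            raise ParameterError("planted_axis_index out of range")
        if self.mapping_family not in MAPPING_FAMILIES:
            raise ParameterError(f"unknown mapping_family {self.mapping_family!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        self.loadings = L

    @property
    def n_latent(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]

    @classmethod
    def default(cls, n_channels: int = 64, n_latent: int = 10, seed: int = 0,
                **kwargs) -> "PlantedGroundTruth":
        """Random orthonormal loadings; planted variance share ~10%."""
        if n_channels < n_latent:
            raise DimensionError("n_channels must be >= n_latent")
        rng = rng_from(seed, "truth")
        q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_latent)))
        return cls(loadings=q, **kwargs)

    def to_json(self, path) -> None:
        rec = dataclasses.asdict(self)
        rec["loadings"] = np.asarray(self.loadings).tolist()
        Path(path).write_text(json.dumps(rec))


@dataclass
class JudgmentMatrix:
    """Binary pairwise size-judgment matrix: entry (i, j) = 1 iff object i
    was judged bigger than object j.  Antisymmetric off the zero diagonal."""

    indicator: np.ndarray
    n_objects: int

    def __post_init__(self):
        ind = np.asarray(self.indicator)
        if ind.shape != (self.n_objects, self.n_objects):
            raise DimensionError("indicator must be n_objects x n_objects")
        if np.any(np.diag(ind) != 0):
            raise ParameterError("indicator diagonal must be zero")
        off = ~np.eye(self.n_objects, dtype=bool)
        if not np.all(ind[off] + ind.T[off] == 1):
            raise ParameterError("indicator must satisfy I_ij + I_ji = 1 off-diagonal")
        self.indicator = ind.astype(int)

    @property
    def n_comparisons(self) -> int:
        """Number of unordered pairs instantiated: n(n-1)/2."""
        return self.n_objects * (self.n_objects - 1) // 2


def size_rank_edges(size_range_cm, n_ranks: int) -> np.ndarray:
    """Log-spaced bin edges (length n_ranks + 1) in cm."""
    lo, hi = size_range_cm
    if not (lo > 0 and hi > lo):
        raise ParameterError("size range must satisfy 0 < lo < hi")
    return np.logspace(np.log10(lo), np.log10(hi), n_ranks + 1)


def mapping_transform(family: str):
    """The stimulus transform g for each candidate mapping family."""
    g = {
        "linear": lambda s: s,
        "pow033": lambda s: np.power(s, 0.33),
        "pow05": lambda s: np.sqrt(s),
        "pow2": lambda s: np.square(s),
        "pow3": lambda s: np.power(s, 3.0),
        "log10": np.log10,
    }
    try:
        return g[family]
    except KeyError:
        raise ParameterError(f"unknown mapping family {family!r}") from None


def _radial_profile(family: str, theta: np.ndarray, phi: float, rng) -> np.ndarray:
    """Radial profile r(theta) of an elongated star-convex shape whose long
    axis points along ``phi``.

    Every family is an angular modulation of an ellipse with random
    elongation, so the bounding-box diagonal is (near-)rotation-invariant
    and fixing it does not couple object area to orientation.
    """
    q = rng.uniform(*_ELONGATION)  # short/long axis ratio, size-independent
    t = theta - phi
    r = q / np.sqrt((q * np.cos(t)) ** 2 + np.sin(t) ** 2)  # ellipse a=1, b=q
    if family == "ellipse":
        mod = np.zeros_like(t)
    elif family == "rectangle":
        # boxier corners: push the ellipse toward a rounded rectangle
        mod = rng.uniform(0.08, 0.16) * np.cos(4 * (t + rng.uniform(0, 2 * np.pi)))
    elif family == "polygon":
        m = rng.integers(5, 9)
        mod = rng.uniform(0.06, 0.12) * np.cos(m * (t + rng.uniform(0, 2 * np.pi)))
    elif family == "star":
        p = rng.integers(5, 8)
        mod = rng.uniform(0.12, 0.22) * np.cos(p * (t + rng.uniform(0, 2 * np.pi)))
    else:  # pragma: no cover
        raise ParameterError(f"unknown shape family {family!r}")
    # low-amplitude boundary ripple for naturalism, frequency independent of u
    k = rng.integers(6, 13)
    r = r * (1.0 + mod + 0.02 * np.cos(k * (t + rng.uniform(0, 2 * np.pi))))
    return r


def _render_stimulus(u: float, image_px: int, diag_px: float, rng) -> tuple[np.ndarray, int]:
    """Render one object; u in [0,1] is the normalized log-size.

    The long-axis orientation and the interior grating wavelength are
    deterministic functions of u; everything else (base shape, elongation,
    grating orientation, phases) is drawn independently of u.
    """
    fam_idx = int(rng.integers(len(_SHAPE_FAMILIES)))
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    phi = u * _ORIENT_SWEEP + rng.normal(0.0, _ORIENT_JITTER)
    r = _radial_profile(_SHAPE_FAMILIES[fam_idx], theta, phi, rng)

    x = r * np.cos(theta)
    y = r * np.sin(theta)
    span = np.hypot(x.max() - x.min(), y.max() - y.min())
    scale = diag_px / span
    cx = cy = image_px / 2.0
    rows = cy + scale * y
    cols = cx + scale * x

    img = np.ones((image_px, image_px), dtype=float)
    rr, cc = draw_polygon(rows, cols, shape=img.shape)

    lam = _TEXTURE_WAVELEN_PX[0] * (_TEXTURE_WAVELEN_PX[1] / _TEXTURE_WAVELEN_PX[0]) ** u
    # grain runs roughly along the object's long axis (wood-grain/fur-like),
    # so oriented texture statistics reinforce the shape's orientation cue
    ori = phi + rng.normal(0.0, _TEXTURE_ORI_JITTER)
    psi = rng.uniform(0, 2 * np.pi)
    # per-stimulus gray level and contrast are size-independent nuisances:
    # they decorrelate the histogram from size and keep any single direction
    # of a generic encoder's response space from aligning with the size cue
    base = rng.uniform(*_TEXTURE_BASE)
    amp = rng.uniform(*_TEXTURE_AMP)
    grating = base + amp * np.sin(
        2 * np.pi * (rr * np.cos(ori) + cc * np.sin(ori)) / lam + psi)
    img[rr, cc] = grating
    return np.clip(img, 0.0, 1.0), fam_idx


def generate_size_stimuli(n_ranks: int = 8, n_per_rank: int = 6, image_px: int = 64,
                          retinal_mode: str = "fixed",
                          size_range_cm: tuple[float, float] = (1.0, 1e4),
                          seed: int = 0) -> SizeRankedStimuli:
    """Generate a size-ranked stimulus set.

    Sizes are stratified log-uniform: each of the ``n_ranks`` log-spaced bins
    over ``size_range_cm`` receives exactly ``n_per_rank`` draws, so the
    marginal distribution is log-uniform and every rank is occupied.

    Parameters
    ----------
    retinal_mode:
        ``"fixed"`` draws every object at the same bounding-box diagonal
        (retinal size decoupled from real-world size); ``"proportional"``
        scales the diagonal with log size.
    """
    if n_ranks < 2:
        raise ParameterError("n_ranks must be >= 2")
    if n_per_rank < 1:
        raise ParameterError("n_per_rank must be >= 1")
    if retinal_mode not in ("fixed", "proportional"):
        raise ParameterError(f"unknown retinal_mode {retinal_mode!r}")
    edges = size_rank_edges(size_range_cm, n_ranks)
    log_edges = np.log10(edges)

    rng = rng_from(seed, "stimuli")
    sizes, ranks = [], []
    for r in range(1, n_ranks + 1):
        lo, hi = log_edges[r - 1], log_edges[r]
        sizes.extend(10 ** rng.uniform(lo, hi, size=n_per_rank))
        ranks.extend([r] * n_per_rank)
    sizes = np.asarray(sizes)
    ranks = np.asarray(ranks, dtype=int)
    u = (np.log10(sizes) - log_edges[0]) / (log_edges[-1] - log_edges[0])

    if retinal_mode == "fixed":
        diag = np.full(len(sizes), 0.72 * image_px)
    else:
        diag = (0.40 + 0.45 * u) * image_px
    # small size-independent jitter (well inside the fixed-mode 5% band)
    diag = diag * (1.0 + rng.uniform(-_DIAG_JITTER, _DIAG_JITTER, len(sizes)))

    images = np.empty((len(sizes), image_px, image_px))
    fams = np.empty(len(sizes), dtype=int)
    for i in range(len(sizes)):
        images[i], fams[i] = _render_stimulus(u[i], image_px, diag[i], rng)

    # category is partially size-informed: shape family crossed with a coarse
    # small/big split, as everyday categories covary with size
    category = fams * 2 + (u >= 0.5).astype(int)
    animate = rng.random(len(sizes)) < 0.5

    return SizeRankedStimuli(images=images, sizes_cm=sizes, ranks=ranks,
                             category=category, animate=animate,
                             retinal_diag_px=diag, n_ranks=n_ranks,
                             size_range_cm=(float(size_range_cm[0]), float(size_range_cm[1])))


def generate_planted_activations(stimuli: SizeRankedStimuli, n_channels: int = 64,
                                 truth: PlantedGroundTruth | None = None,
                                 seed: int = 0):
    """Planted-axis activations: ``X = C @ loadings.T + E``.

    The planted latent score is ``beta * g(size) + eps`` with ``g`` the
    mapping-family transform *standardized over the stimulus sample* (zero
    mean, unit sd): an axis carries deviations around the population
    baseline, which keeps the planted-axis variance exactly ``beta**2`` and
    the similarity structure of the rank means a function of rank distance
    rather than of absolute response level.  ``eps`` has sd
    ``truth.noise_sd``; the other latent scores are standard normal; ``E``
    is i.i.d. Gaussian channel noise with sd ``truth.noise_sd``.

    Returns a :class:`sizeaxis.encoder.ResponseMatrix` aligned with
    ``stimuli``.
    """
    from .encoder import ResponseMatrix

    if truth is None:
        truth = PlantedGroundTruth.default(n_channels=n_channels,
                                           seed=child_seed(seed, "default-truth"))
    if n_channels != truth.n_channels:
        raise DimensionError("n_channels does not match truth.loadings")
    if n_channels < truth.n_latent:
        raise DimensionError("n_channels must be >= n_latent")

    rng = rng_from(seed, "activations")
    n = len(stimuli)
    g = mapping_transform(truth.mapping_family)(np.asarray(stimuli.sizes_cm, dtype=float))
    g_sd = g.std()
    if g_sd == 0:
        raise ParameterError("sizes give a constant transformed value")
    g = (g - g.mean()) / g_sd
    scores = rng.standard_normal((n, truth.n_latent))
    scores[:, truth.planted_axis_index - 1] = (truth.beta * g
                                               + truth.noise_sd * rng.standard_normal(n))
    X = scores @ truth.loadings.T
    X += truth.noise_sd * rng.standard_normal(X.shape)
    return ResponseMatrix(values=X, stimulus_ids=stimuli.ids)


def generate_pairwise_judgments(sizes_cm, weber_noise: float = 0.0,
                                seed: int = 0) -> JudgmentMatrix:
    """Simulate all-pairs bigger/smaller judgments over one object set.

    Each of the n(n-1)/2 unordered pairs is judged once; object ``i`` beats
    ``j`` with probability ``Phi((log s_i - log s_j) / weber_noise)`` — a
    probit choice model on log-size differences, consistent with Weber-law
    discrimination.  With ``weber_noise = 0`` the comparison is the
    deterministic truth (ties broken toward the higher index).
    """
    sizes = np.asarray(sizes_cm, dtype=float)
    if sizes.ndim != 1 or len(sizes) < 2:
        raise ParameterError("need at least 2 objects")
    if np.any(sizes <= 0):
        raise ParameterError("sizes must be positive")
    if weber_noise < 0:
        raise ParameterError("weber_noise must be nonnegative")

    n = len(sizes)
    rng = rng_from(seed, "judgments")
    ind = np.zeros((n, n), dtype=int)
    logs = np.log(sizes)
    for i in range(n):
        for j in range(i + 1, n):
            if weber_noise == 0:
                i_wins = logs[i] > logs[j]
            else:
                p = norm.cdf((logs[i] - logs[j]) / weber_noise)
                i_wins = rng.random() < p
            if i_wins:
                ind[i, j] = 1
            else:
                ind[j, i] = 1
    return JudgmentMatrix(indicator=ind, n_objects=n)


# ---------------------------------------------------------------------------
# External interfaces: stimulus manifest + PNG export, CSV/JSON round-trips

def write_stimuli(stimuli: SizeRankedStimuli, outdir) -> Path:
    """Write 8-bit grayscale PNGs plus a TSV manifest; returns manifest path."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(stimuli.ids):
        img8 = np.round(stimuli.images[i] * 255).astype(np.uint8)
        fname = f"{sid}.png"
        Image.fromarray(img8, mode="L").save(outdir / fname)
        rows.append(dict(id=sid, image=fname, size_cm=stimuli.sizes_cm[i],
                         rank=int(stimuli.ranks[i]), category=int(stimuli.category[i]),
                         animate=bool(stimuli.animate[i]),
                         retinal_diag_px=float(stimuli.retinal_diag_px[i])))
    manifest = outdir / "stimuli.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_judgments(j: JudgmentMatrix, path) -> None:
    pd.DataFrame(j.indicator).to_csv(path, index=False)


def read_judgments(path) -> JudgmentMatrix:
    ind = pd.read_csv(path).to_numpy(dtype=int)
    return JudgmentMatrix(indicator=ind, n_objects=ind.shape[0])
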