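"""End-to-end orchestration: simulate -> transform -> encode -> RSA ->
object space -> dropout -> mapping -> ablation -> independence checks.

A :class:`RunConfig` fully determines a run; every stage's randomness is
derived from the single top-level seed, so reports are byte-identical across
repeated runs.  The primary analysis responses come either from the built-in
encoder shown the original stimuli (``data_source="encoder"``) or from the
planted-axis generator (``data_source="planted"``, the default study
condition with a known log10 ground truth); the four-condition
correspondence profile (original / silhouette / texture / shuffle) is always
computed with the stimulus encoder.

Null-distribution encodings are computed once per repetition and shared
between the dropout-significance and ablation nulls (stage caching), which
is what makes hundreds of null encoders affordable.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._utils import child_seed
from .encoder import ResponseMatrix, build_encoder, encode, fit_readout, readout_accuracy
from .errors import ParameterError, SchemaError
from .mapping import feature_axis_correlation, select_mapping
from .neuro_stats import group_difference
from .object_space import (build_object_space, dropout_significance,
                           orient_axis_to_log_size, remove_axis_variance,
                           remove_direction_variance)
from .rsa import ideal_observer_rsm, rank_rsm, rsm_correspondence
from .synthetic import (PlantedGroundTruth, generate_planted_activations,
                        generate_size_stimuli, size_rank_edges, write_stimuli)
from .transforms import make_silhouette, aspect_ratio, transform_stimuli

CONDITIONS = ("original", "silhouette", "texture", "shuffle")


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    # stimuli
    n_ranks: int = 8
    n_per_rank: int = 6
    image_px: int = 64
    retinal_mode: str = "fixed"
    size_range_cm: tuple[float, float] = (1.0, 1e4)
    # primary data source
    data_source: str = "planted"      # "planted" | "encoder"
    n_channels: int = 64
    n_latent: int = 10
    beta: float = 2.0
    noise_sd: float = 0.25
    mapping_family: str = "log10"
    # analysis
    var_threshold: float = 0.9
    n_null_reps: int = 200
    alpha: float = 0.05
    mapping_direction: str = "score_on_size"
    # stimulus encoder (condition profile; also the primary encoder when
    # data_source == "encoder")
    encoder_layers: tuple[int, ...] = (12, 24, 48)
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_range_cm"] = list(self.size_range_cm)
        d["encoder_layers"] = list(self.encoder_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "size_range_cm" in d:
            d["size_range_cm"] = tuple(d["size_range_cm"])
        if "encoder_layers" in d:
            d["encoder_layers"] = tuple(d["encoder_layers"])
        return cls(**d)

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Every number a run produces, recomputable from the manifest alone."""

    config_hash: str
    seed: int
    correspondence: dict          # condition -> r vs ideal observer
    reference_r: float            # primary responses vs ideal observer
    identified_axis: int | None   # 1-based PC ordinal, None when no axis found
    n_significant: int
    di_table: list                # per axis: {axis, di, p, significant}
    best_mapping: dict            # {family, slope, intercept, r2}
    mapping_table: list
    ablation: dict                # {acc_full, acc_ablated, p}
    independence: dict            # curvature/animacy statistics
    package_version: str = ""

    REQUIRED = ("config_hash", "seed", "correspondence", "reference_r",
                "identified_axis", "n_significant", "di_table", "best_mapping",
                "mapping_table", "ablation", "independence", "package_version")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.REQUIRED}


def _check_finite(obj, path="report"):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise SchemaError(f"non-finite statistic at {path}")


def write_report(report: RunReport, path) -> None:
    """Write the report as JSON plus a human-readable summary.

    Validates the schema: every field present, every statistic finite.
    """
    if not isinstance(report, RunReport):
        raise SchemaError("write_report expects a RunReport")
    d = report.to_dict()
    for k in RunReport.REQUIRED:
        if d.get(k, None) is None and k not in ("identified_axis",):
            raise SchemaError(f"missing report field {k!r}")
    _check_finite(d)
    path = Path(path)
    path.write_text(json.dumps(d, indent=2, sort_keys=True))

    lines = [f"sizeaxis run report (seed {report.seed}, config {report.config_hash})",
             f"  ideal-observer correspondence: " +
             ", ".join(f"{c}={report.correspondence[c]:.3f}" for c in report.correspondence),
             f"  primary responses r = {report.reference_r:.3f}",
             f"  significant axes: {report.n_significant} "
             f"(identified: {'PC%d' % report.identified_axis if report.identified_axis else 'none'})",
             f"  best mapping: {report.best_mapping['family']} "
             f"(R^2 = {report.best_mapping['r2']:.3f})",
             f"  ablation: top-1 {report.ablation['acc_full']:.3f} -> "
             f"{report.ablation['acc_ablated']:.3f} (p = {report.ablation['p']:.4g})"]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def read_report(path) -> RunReport:
    d = json.loads(Path(path).read_text())
    missing = [k for k in RunReport.REQUIRED if k not in d]
    if missing:
        raise SchemaError(f"missing report fields {missing}")
    return RunReport(**{k: d[k] for k in RunReport.REQUIRED})


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage of the analysis; deterministic per seed."""
    from . import __version__

    cfg = config
    seed = cfg.seed
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    stimuli = generate_size_stimuli(cfg.n_ranks, cfg.n_per_rank, cfg.image_px,
                                    cfg.retinal_mode, cfg.size_range_cm,
                                    seed=child_seed(seed, "stimuli"))
    ranks = stimuli.ranks
    ideal = ideal_observer_rsm(cfg.n_ranks)

    # --- transform + encode the four conditions ----------------------------
    enc = build_encoder(n_layers=len(cfg.encoder_layers),
                        channels_per_layer=cfg.encoder_layers,
                        image_px=cfg.image_px, seed=child_seed(seed, "encoder"))
    correspondence = {}
    cond_responses = {}
    for cond in CONDITIONS:
        imgs = transform_stimuli(stimuli, cond, seed=child_seed(seed, "transform", cond))
        resp = encode(enc, imgs)
        cond_responses[cond] = resp
        correspondence[cond] = rsm_correspondence(rank_rsm(resp, ranks), ideal)

    # --- primary responses --------------------------------------------------
    if cfg.data_source == "planted":
        truth = PlantedGroundTruth.default(
            n_channels=cfg.n_channels, n_latent=cfg.n_latent,
            seed=child_seed(seed, "truth"), beta=cfg.beta,
            noise_sd=cfg.noise_sd, mapping_family=cfg.mapping_family)
        responses = generate_planted_activations(stimuli, cfg.n_channels, truth,
                                                 seed=child_seed(seed, "planted"))
    elif cfg.data_source == "encoder":
        responses = cond_responses["original"]
    else:
        raise ParameterError(f"unknown data_source {cfg.data_source!r}")

    # --- shared null encodings (cached across dropout and ablation) --------
    null_cfg = dict(n_layers=2, channels_per_layer=(8, responses.channel_count),
                    kernel_px=5)
    _null_cache: dict[int, ResponseMatrix] = {}

    def null_responses_fn(rep_seed):
        if rep_seed not in _null_cache:
            null_enc = build_encoder(image_px=cfg.image_px, seed=rep_seed, **null_cfg)
            _null_cache[rep_seed] = encode(null_enc, stimuli)
        return _null_cache[rep_seed]

    # --- object space + dropout statistics ----------------------------------
    space, scores = build_object_space(responses, cfg.var_threshold)
    dropout = dropout_significance(responses, ranks,
                                   null_responses_fn=null_responses_fn,
                                   var_threshold=cfg.var_threshold,
                                   n_null_reps=cfg.n_null_reps, alpha=cfg.alpha,
                                   seed=child_seed(seed, "dropout"))
    sig = dropout.significant_axes()
    if sig:
        identified = int(max(sig, key=lambda a: dropout.di[a - 1]))
    else:
        identified = None
    # the axis submitted to the mapping analysis: the identified one, else
    # the largest-DI axis (its mapping R^2 then reports how little any axis
    # carries size)
    mapping_axis = identified or int(np.argmax(dropout.di) + 1)
    axis_scores = orient_axis_to_log_size(scores, mapping_axis, stimuli.sizes_cm)

    best, table = select_mapping(axis_scores, stimuli.sizes_cm,
                                 direction=cfg.mapping_direction)

    # --- ablation of recognition -------------------------------------------
    model = fit_readout(enc, responses, stimuli.category)
    acc_full = readout_accuracy(model, responses, stimuli.category)
    ablated = remove_axis_variance(responses, space, mapping_axis)
    acc_abl = readout_accuracy(model, ablated, stimuli.category)
    drops = []
    for rep in range(cfg.n_null_reps):
        resp0 = null_responses_fn(child_seed(child_seed(seed, "dropout"), "null", rep))
        space0, _ = build_object_space(resp0, cfg.var_threshold)
        for i in range(space0.n_retained):
            resid = remove_direction_variance(responses, space, space0.axes[:, i])
            drops.append(acc_full - readout_accuracy(model, resid, stimuli.category))
    drops = np.asarray(drops)
    abl_p = float((np.sum(drops >= acc_full - acc_abl) + 1.0) / (len(drops) + 1.0))

    # --- independence: curvature and animacy --------------------------------
    curvature = np.array([aspect_ratio(make_silhouette(img))
                          for img in stimuli.images])
    ind_seed = child_seed(seed, "independence")
    curv_size = feature_axis_correlation(np.log10(stimuli.sizes_cm), curvature,
                                         seed=ind_seed)
    curv_axis = feature_axis_correlation(axis_scores, curvature, seed=ind_seed + 1)
    pc1 = scores.axis(1)
    animate = stimuli.animate.astype(bool)
    anim_pc1 = group_difference(pc1[animate], pc1[~animate], seed=ind_seed + 2)
    anim_axis = group_difference(axis_scores[animate], axis_scores[~animate],
                                 seed=ind_seed + 3)

    report = RunReport(
        config_hash=cfg.config_hash(), seed=seed,
        correspondence={c: float(correspondence[c]) for c in CONDITIONS},
        reference_r=float(dropout.reference_r),
        identified_axis=identified, n_significant=len(sig),
        di_table=[dict(axis=i + 1, di=float(dropout.di[i]),
                       p=float(dropout.p_corrected[i]),
                       significant=bool(dropout.significant[i]))
                  for i in range(dropout.n_retained)],
        best_mapping=dict(family=best.family, slope=best.slope,
                          intercept=best.intercept, r2=best.r2),
        mapping_table=table.to_dict(orient="records"),
        ablation=dict(acc_full=float(acc_full), acc_ablated=float(acc_abl), p=abl_p),
        independence=dict(curvature_vs_size=curv_size,
                          curvature_vs_axis=curv_axis,
                          animacy_vs_pc1=anim_pc1,
                          animacy_vs_size_axis=anim_axis),
        package_version=__version__)

    if outdir:
        manifest = dict(config=cfg.to_dict(), config_hash=cfg.config_hash(),
                        package_version=__version__,
                        rank_bin_edges_cm=size_rank_edges(cfg.size_range_cm,
                                                          cfg.n_ranks).tolist(),
                        derived_seeds={k: child_seed(seed, k) for k in
                                       ("stimuli", "encoder", "truth", "planted",
                                        "dropout", "independence")})
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        write_stimuli(stimuli, outdir / "stimuli")
        responses.to_csv(outdir / "responses.csv")
        rank_rsm(responses, ranks).to_csv(outdir / "rsm_primary.csv")
        space.save(outdir / "space_axes.csv", outdir / "space_meta.json")
        dropout.save(outdir / "dropout.json", outdir / "dropout_null.csv")
        table.to_csv(outdir / "mapping_table.csv", index=False)
        write_report(report, outdir / "report.json")
    return report
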