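"""Stimulus-to-representation mapping laws and feature-axis correlations.

Six candidate mapping families relate physical size to the scores on a
representational axis: linear, three power laws (exponents 0.33, 0.5, 2, 3)
and the common logarithm.  Each is fit by ordinary least squares of the axis
score on the transformed size, ``score = a * g(size) + b``; since every
family has the same two free parameters, families are compared by raw R².
Selection of the logarithmic family is the signature of Weber–Fechner
(compressive) coding of a quantity spanning orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from
from .errors import ParameterError, UndefinedStatisticError
from .synthetic import MAPPING_FAMILIES, mapping_transform


@dataclass
class MappingFit:
    """OLS fit of axis scores on one transformed-size family."""

    family: str
    slope: float
    intercept: float
    r2: float
    n: int


def fit_mapping_family(axis_scores, sizes_cm, family: str,
                       direction: str = "score_on_size") -> MappingFit:
    """Fit one mapping family by simple linear regression.

    ``direction="score_on_size"`` (default) regresses the axis score on
    ``g(size)``, which is well defined for every family; the as-printed
    alternative ``"size_on_score"`` regresses transformed *size-axis reading*
    the other way (``g`` applied to the score, clipped to its domain) for
    users who want the textbook orientation.  R² is identical for the two
    directions of a simple regression with an invertible transform.
    """
    y = np.asarray(axis_scores, dtype=float)
    s = np.asarray(sizes_cm, dtype=float)
    if y.shape != s.shape or y.ndim != 1 or len(y) < 3:
        raise ParameterError("need aligned 1-D inputs of length >= 3")
    if np.any(s <= 0) and family != "linear":
        raise ParameterError(f"family {family!r} requires positive sizes")
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("axis scores are constant: fit undefined")

    g = mapping_transform(family)
    if direction == "score_on_size":
        x, target = g(s), y
    elif direction == "size_on_score":
        eps = 1e-9
        x, target = g(np.maximum(y, eps) if family in ("pow033", "pow05", "log10")
                      else y), s
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("transformed predictor is constant")
    res = stats.linregress(x, target)
    return MappingFit(family=family, slope=float(res.slope),
                      intercept=float(res.intercept),
                      r2=float(res.rvalue ** 2), n=len(y))


def select_mapping(axis_scores, sizes_cm, direction: str = "score_on_size"
                   ) -> tuple[MappingFit, pd.DataFrame]:
    """Fit all six families and return the best by R² plus the full table.

    Ties are broken toward the simpler family in the canonical order
    (linear, pow033, pow05, pow2, pow3, log10).
    """
    fits = [fit_mapping_family(axis_scores, sizes_cm, fam, direction)
            for fam in MAPPING_FAMILIES]
    table = pd.DataFrame([vars(f) for f in fits])
    best = max(fits, key=lambda f: f.r2)  # max keeps the first on ties
    return best, table


def feature_axis_correlation(axis_scores, feature, n_perm: int = 1000,
                             seed: int = 0) -> dict:
    """Pearson correlation between an axis and a stimulus feature, with a
    two-sided permutation p-value (feature values permuted across stimuli).
    """
    x = np.asarray(axis_scores, dtype=float)
    f = np.asarray(feature, dtype=float)
    if x.shape != f.shape or len(x) < 3:
        raise ParameterError("need aligned 1-D inputs of length >= 3")
    if np.ptp(x) == 0 or np.ptp(f) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, f)[0, 1])
    rng = rng_from(seed, "feature-perm")
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.corrcoef(x, rng.permutation(f))[0, 1]
    p = float((np.sum(np.abs(null) >= abs(r)) + 1.0) / (n_perm + 1.0))
    return dict(r=r, r2=r * r, p=p)
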