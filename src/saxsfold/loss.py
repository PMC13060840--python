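"""SAXS losses and profile-fit discrepancy.

Three pieces: the area-weighted L1 distance between two normalized P(r)
curves (the experimental-guidance term used during training and
inference-time optimization), the composite training loss that combines it
with the five standard structure-prediction loss components under fixed
weights, and the chi-square discrepancy between a model and an experimental
scattering profile with a closed-form linear scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import (
    ContractViolationError,
    DegenerateFitError,
    InvalidParameterError,
    MissingTermError,
)
from .profile import PrCurve, ScatteringProfile, resample_pr


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite training loss.

    Defaults: total = 0.5*L_FAPE + 0.5*L_aux + 0.3*L_dist + 2.0*L_msa
    + 0.01*L_conf + 2.0*L_SAXS.
    """

    w_fape: float = 0.5
    w_aux: float = 0.5
    w_dist: float = 0.3
    w_msa: float = 2.0
    w_conf: float = 0.01
    w_saxs: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise InvalidParameterError(f"{f.name} must be non-negative")


@dataclass(frozen=True)
class CompositeLossReport:
    """Component loss values and their weighted total."""

    fape: float
    aux: float
    dist: float
    msa: float
    conf: float
    saxs: float
    total: float
    weights: LossWeights


COMPONENT_NAMES = ("fape", "aux", "dist", "msa", "conf", "saxs")


def common_grid(a: PrCurve, b: PrCurve) -> np.ndarray:
    """Shared bin centers: the finer bin width, spanning both supports."""
    dr = min(a.dr, b.dr)
    r_max = max(a.r[-1], b.r[-1])
    n = int(np.floor(r_max / dr)) + 1
    return (np.arange(n) + 0.5) * dr


def saxs_l1(pred: PrCurve, target: PrCurve) -> float:
    """Area-weighted L1 distance between two normalized P(r) curves.

    sum_k |p_pred - p_target| * dr over a common grid (the coarser curve is
    resampled onto the finer one).  Symmetric, zero iff the curves agree on
    the shared grid, and bounded by 2 for unit-area densities.
    """
    if not (pred.normalized and target.normalized):
        raise ContractViolationError("saxs_l1 requires normalized curves")
    if pred.r.shape == target.r.shape and np.allclose(pred.r, target.r, atol=1e-9):
        a, b, dr = pred.p, target.p, pred.dr
    else:
        grid = common_grid(pred, target)
        a = resample_pr(pred, grid).p
        b = resample_pr(target, grid).p
        dr = float(grid[1] - grid[0])
    return float(np.abs(a - b).sum() * dr)


def saxs_l1_grad(pred_p: np.ndarray, target_p: np.ndarray, dr: float) -> np.ndarray:
    """d(saxs_l1)/d(pred_p) for curves already on one grid: sign(p - t) * dr."""
    return np.sign(np.asarray(pred_p) - np.asarray(target_p)) * dr


def composite_loss(
    components: dict[str, float],
    weights: LossWeights | None = None,
) -> CompositeLossReport:
    """Weighted sum of the six training-loss components.

    ``components`` must supply all of ``fape, aux, dist, msa, conf, saxs`` as
    finite scalars; a missing term raises rather than silently contributing
    zero.
    """
    weights = weights or LossWeights()
    vals = {}
    for name in COMPONENT_NAMES:
        if name not in components:
            raise MissingTermError(f"loss component {name!r} not supplied")
        v = float(components[name])
        if not np.isfinite(v):
            raise InvalidParameterError(f"loss component {name!r} is not finite")
        vals[name] = v
    unknown = set(components) - set(COMPONENT_NAMES)
    if unknown:
        raise InvalidParameterError(f"unknown loss components: {sorted(unknown)}")
    total = (
        weights.w_fape * vals["fape"] + weights.w_aux * vals["aux"]
        + weights.w_dist * vals["dist"] + weights.w_msa * vals["msa"]
        + weights.w_conf * vals["conf"] + weights.w_saxs * vals["saxs"]
    )
    return CompositeLossReport(total=total, weights=weights, **vals)


def chi2_fit(
    model: ScatteringProfile,
    experiment: ScatteringProfile,
) -> tuple[float, float]:
    """Scale a model profile onto an experiment and report the discrepancy.

    The scale c minimizing sum(((I_exp - c*I_mod)/sigma)^2) has the closed
    form c = sum(I_exp*I_mod/sigma^2) / sum(I_mod^2/sigma^2); the returned
    chi-square is averaged over the N experimental points.  The model is
    linearly interpolated onto the experimental q grid if the grids differ.
    """
    if experiment.sigma is None:
        raise InvalidParameterError("experimental profile carries no uncertainties")
    if model.q.shape == experiment.q.shape and np.allclose(model.q, experiment.q):
        i_mod = model.i
    else:
        i_mod = np.interp(experiment.q, model.q, model.i)
    i_exp, sig = experiment.i, experiment.sigma
    denom = float((i_mod ** 2 / sig ** 2).sum())
    if denom <= 0:
        raise DegenerateFitError("model profile is identically zero; no scale exists")
    c = float((i_exp * i_mod / sig ** 2).sum()) / denom
    chi2 = float((((i_exp - c * i_mod) / sig) ** 2).mean())
    return c, chi2
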