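"""Correction for girdle-induced resin loss in inoculated+girdled trees.

Girdling alone bleeds resin from the wound, deflating the measured
post-treatment terpene pool.  The correction is estimated from the
girdled-only (noninoculated) trees: their relative MST change over the
inoculation period, regressed on predawn water potential (watered trees lose
more resin than droughted ones), predicts the relative loss for each
inoculated+girdled tree, clipped to [-1, 0].  Two application conventions
are provided:

``printed``
    delta_corrected = delta_raw * (1 + correction)  (the default).
``add_back_absolute``
    delta_corrected = delta_raw - correction * mst_pre, i.e. the absolute
    concentration lost is added back.

The two disagree in sign behaviour for positive raw inductions; both are
kept and every output labels which was used.  Conclusions drawn downstream
should be checked under both (they were similar in the motivating study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Cohort, TreeRecord, ValidationError

__all__ = [
    "CorrectionModel",
    "InductionChange",
    "delta_mst",
    "relative_mst_change",
    "fit_loss_model",
    "predict_correction",
    "apply_correction",
    "correct_cohort",
]

CLIP_BOUNDS = (-1.0, 0.0)


class InsufficientDataError(ValueError):
    """Too few usable girdled-only trees to fit the loss model."""


class SingularFitError(ValueError):
    """No variance in the predictor; the loss line is not identifiable."""


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted linear relation between drought stress and relative girdle loss.

    The predictor is drought-stress magnitude, -psi_pd (MPa), so
    ``slope`` > 0 means droughted trees lose *less* resin:
    predicted loss = intercept + slope * (-psi_pd).
    """

    intercept: float
    slope: float  # relative loss per MPa of drought stress (-psi_pd)
    n: int
    residual_sd: float
    r_squared: float
    se_intercept: float = float("nan")
    se_slope: float = float("nan")
    clip_bounds: tuple[float, float] = CLIP_BOUNDS

    def predict(self, psi_pd):
        return predict_correction(self, psi_pd)


@dataclass(frozen=True)
class InductionChange:
    """Raw and girdle-corrected change in MST for one tree."""

    tree_id: str
    delta_t_raw: float
    correction: float
    delta_t_corrected: float
    convention: str


def delta_mst(mst_pre: float, mst_post: float | None) -> float:
    """Post- minus pre-inoculation MST concentration (mg g^-1; may be < 0).

    A missing ``mst_post`` raises so the caller excludes the tree explicitly
    instead of zero-filling.
    """
    if mst_post is None:
        raise ValidationError("mst_post missing; tree must be excluded, not zeroed")
    if mst_pre < 0 or mst_post < 0:
        raise ValidationError("MST concentrations must be >= 0")
    return mst_post - mst_pre


def relative_mst_change(mst_pre: float, mst_post: float | None,
                        tree_id: str = "?") -> float:
    """(post - pre) / pre; requires a positive pre-inoculation pool."""
    if mst_pre <= 0:
        raise ValidationError(
            f"{tree_id}: relative MST change undefined for mst_pre={mst_pre}"
        )
    return delta_mst(mst_pre, mst_post) / mst_pre


def fit_loss_model(girdled_noninoculated: Cohort | list[TreeRecord]) -> CorrectionModel:
    """OLS of relative MST change on psi_pd over girdled-only trees.

    Only girdled, noninoculated trees with both MST timepoints and a positive
    pre pool are usable; fewer than three raises.
    """
    trees = list(girdled_noninoculated)
    usable = [
        t for t in trees
        if t.girdled and not t.inoculated and t.has_post and t.mst_pre > 0
    ]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 girdled noninoculated trees with pre/post MST, "
            f"got {len(usable)}"
        )
    x = np.array([-t.psi_pd for t in usable])  # drought-stress magnitude
    y = np.array([relative_mst_change(t.mst_pre, t.mst_post, t.tree_id)
                  for t in usable])
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in psi_pd among girdled trees")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(usable) - 2
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    sigma2 = ss_res / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return CorrectionModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        n=len(usable),
        residual_sd=float(np.sqrt(sigma2)),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=float(np.sqrt(cov[1, 1])),
    )


def predict_correction(model: CorrectionModel, psi_pd):
    """Predicted relative girdle loss at psi_pd, clipped to [-1, 0].

    A predicted relative *gain* is treated as "no loss" (clip ceiling 0);
    losses below -1 are physically impossible (clip floor -1).
    """
    raw = model.intercept + model.slope * (-np.asarray(psi_pd, dtype=float))
    clipped = np.clip(raw, *model.clip_bounds)
    return float(clipped) if np.isscalar(psi_pd) else clipped


def apply_correction(
    delta_t_raw: float,
    correction: float,
    convention: str = "printed",
    mst_pre: float | None = None,
) -> float:
    """Girdle-corrected induced MST change under the chosen convention."""
    if not (CLIP_BOUNDS[0] <= correction <= CLIP_BOUNDS[1]):
        raise ValueError(f"correction {correction} outside {CLIP_BOUNDS}")
    if convention == "printed":
        return delta_t_raw * (1.0 + correction)
    if convention == "add_back_absolute":
        if mst_pre is None:
            raise ValueError("add_back_absolute convention requires mst_pre")
        return delta_t_raw - correction * mst_pre
    raise ValueError(f"unknown convention {convention!r}")


def correct_cohort(
    cohort: Cohort,
    model: CorrectionModel | None = None,
    convention: str = "printed",
) -> list[InductionChange]:
    """Per-tree raw and corrected MST changes for a whole cohort.

    The correction applies only to inoculated+girdled trees; every other
    tree passes through with correction 0.  Trees without post tissue are
    skipped (they carry no delta).  ``model=None`` fits the loss model from
    the cohort's own girdled-only trees.
    """
    if model is None:
        model = fit_loss_model(cohort)
    out: list[InductionChange] = []
    for t in cohort:
        if not t.has_post:
            continue
        raw = delta_mst(t.mst_pre, t.mst_post)
        corr = predict_correction(model, t.psi_pd) if (t.girdled and t.inoculated) \
            else 0.0
        out.append(
            InductionChange(
                tree_id=t.tree_id,
                delta_t_raw=raw,
                correction=corr,
                delta_t_corrected=apply_correction(raw, corr, convention, t.mst_pre),
                convention=convention,
            )
        )
    return out
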