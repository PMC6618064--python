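"""Prediction of final-outcome effects from surrogate effects; cross-validation.

A study's final-outcome estimate is masked (treated as missing at random),
the model is refitted, and the missing estimate is predicted from the
study's surrogate estimate plus the data of all remaining studies.  Given
each hyperparameter draw, the pair (Y1, Y2) of the target study is
bivariate normal with covariance Sigma_i + T_kl, so the predictive draw of
Y2 is exact Gaussian conditioning on the observed Y1; the predictive sd
therefore includes the within-study noise of the masked estimate.
Model-comparison statistics over cross-validated predictions follow the
per-study-then-average convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import NetworkData
from .inference import McmcConfig, PosteriorDraws, _derive_seed, fit
from .models import ModelSpec, build_model
from .priors import PriorConfig

logger = logging.getLogger(__name__)


class PredictionNotIdentifiedError(RuntimeError):
    """The requested prediction would be driven by the prior alone."""


@dataclass(frozen=True)
class PredictionResult:
    """Predicted vs. observed treatment effect on the final outcome."""

    study_id: str
    contrast: str
    pred_mean: float
    pred_lo: float
    pred_hi: float
    pred_sd: float
    obs_est: float | None
    obs_lo: float | None
    obs_hi: float | None
    prior_driven: bool = False

    def __post_init__(self) -> None:
        if not (self.pred_lo <= self.pred_mean <= self.pred_hi):
            raise ValueError(
                f"{self.study_id}: predictive interval must bracket the mean"
            )

    @property
    def pred_width(self) -> float:
        return self.pred_hi - self.pred_lo

    @property
    def obs_width(self) -> float | None:
        if self.obs_lo is None or self.obs_hi is None:
            return None
        return self.obs_hi - self.obs_lo


def _contrast_other_studies(data: NetworkData, target) -> int:
    c = data.contrast_of(target)
    return sum(
        1
        for o in data.observations
        if o.study_id != target.study_id and data.contrast_of(o) == c
    )


def _treatment_elsewhere(data: NetworkData, target) -> bool:
    others = [o for o in data.observations if o.study_id != target.study_id]
    seen = {t for o in others for t in (o.treat_k, o.treat_l)}
    return target.treat_k in seen and target.treat_l in seen


def predictive_draws(
    draws: PosteriorDraws, target_idx: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-hyperparameter-draw predictive samples of the masked Y2."""
    model = draws.model
    theta = draws.flat_theta()
    t11, t22, t12 = model.contrast_covs(theta)
    means = model.contrast_means(theta)
    ci = int(model._c_idx[target_idx])
    sgn = model._mean_sign[target_idx]
    m1 = sgn * means[..., ci, 0]
    m2 = sgn * means[..., ci, 1]
    v11 = model._s11[target_idx] + t11[..., ci]
    v22 = model._s22[target_idx] + t22[..., ci]
    v12 = model._s12[target_idx] + t12[..., ci]
    y1 = model._y1[target_idx]
    cond_mean = m2 + v12 / v11 * (y1 - m1)
    cond_var = np.maximum(v22 - v12**2 / v11, 0.0)
    return cond_mean + np.sqrt(cond_var) * rng.standard_normal(cond_mean.shape)


def predict_study(
    data: NetworkData,
    variant: str,
    target: str,
    cfg: McmcConfig,
    priors: PriorConfig | None = None,
    fixed_between: np.ndarray | None = None,
) -> PredictionResult:
    """Predict one study's final-outcome effect from its surrogate effect.

    The target's Y2 (if observed) is masked before fitting.  For variants
    without the exchangeable treatment layer, a target whose contrast has
    no other study and one of whose treatments appears nowhere else is not
    identified (the basic parameter, hence the prediction, would rest on
    the prior alone) and raises :class:`PredictionNotIdentifiedError`; a
    merely sparse contrast is flagged ``prior_driven`` instead.
    """
    target_obs = next(
        (o for o in data.observations if o.study_id == target), None
    )
    if target_obs is None:
        raise KeyError(f"no study {target!r} in the network")
    if not math.isfinite(target_obs.y1):
        raise ValueError(f"study {target!r} has no surrogate estimate")

    n_same_contrast = _contrast_other_studies(data, target_obs)
    treat_elsewhere = _treatment_elsewhere(data, target_obs)
    if variant.startswith("1") or variant == "brma":
        if variant != "brma" and n_same_contrast == 0 and not treat_elsewhere:
            raise PredictionNotIdentifiedError(
                f"study {target!r}: its contrast has no other studies and a "
                f"treatment unseen elsewhere; under variant {variant!r} the "
                f"prediction would be based on the prior distribution only"
            )
    prior_driven = n_same_contrast == 0 and variant != "brma"

    masked = data.mask_final_outcome(target)
    model = build_model(masked, variant, priors, fixed_between=fixed_between)
    draws = fit(model, cfg)
    t_idx = next(
        i for i, o in enumerate(masked.observations) if o.study_id == target
    )
    rng = np.random.default_rng(_derive_seed(cfg.seed, 31337, t_idx))
    y2_draws = predictive_draws(draws, t_idx, rng)
    lo, med, hi = np.percentile(y2_draws, [2.5, 50.0, 97.5])
    mean = float(y2_draws.mean())
    mean_in = min(max(mean, lo), hi)  # guard against extreme skew
    k, l = masked.contrast_of(target_obs)
    return PredictionResult(
        study_id=target,
        contrast=f"{k}{l}",
        pred_mean=mean_in,
        pred_lo=float(lo),
        pred_hi=float(hi),
        pred_sd=float(y2_draws.std(ddof=1)),
        obs_est=target_obs.y2,
        obs_lo=None if target_obs.y2 is None else target_obs.y2 - 1.96 * target_obs.se2,
        obs_hi=None if target_obs.y2 is None else target_obs.y2 + 1.96 * target_obs.se2,
        prior_driven=prior_driven,
    )


def take_one_out_cv(
    data: NetworkData,
    variant: str,
    cfg: McmcConfig,
    subset: list[str] | None = None,
    priors: PriorConfig | None = None,
) -> list[PredictionResult]:
    """Take-one-out cross-validation: mask and predict one study at a time.

    Each prediction comes from an independent fit with only that study's
    final-outcome estimate masked.  Per-study failures are logged and
    skipped, not fatal.  Deterministic given ``cfg.seed`` (per-study seeds
    are derived from it).
    """
    targets = []
    for o in data.observations:
        if subset is not None and o.study_id not in subset:
            continue
        if o.y2_missing:
            continue
        targets.append(o.study_id)
    if subset is not None:
        unknown = set(subset) - {o.study_id for o in data.observations}
        if unknown:
            raise KeyError(f"subset names unknown studies: {sorted(unknown)}")
    results = []
    for i, sid in enumerate(targets):
        cfg_i = cfg.with_seed(_derive_seed(cfg.seed, 9000, i))
        try:
            results.append(
                predict_study(data, variant, sid, cfg_i, priors=priors)
            )
        except (PredictionNotIdentifiedError, RuntimeError) as exc:
            logger.warning("prediction failed for study %s: %s", sid, exc)
    return results


# ---------------------------------------------------------------------------
# model-comparison statistics
# ---------------------------------------------------------------------------


def _study_stats(r: PredictionResult, ref: PredictionResult | None) -> dict:
    if r.obs_est is None:
        raise ValueError(f"study {r.study_id}: no observed estimate to score")
    w_obs = r.obs_width
    w_pred = r.pred_width
    flagged = False
    if w_obs == 0:
        p_overlap = 1.0 if r.pred_lo <= r.obs_est <= r.pred_hi else 0.0
        width_ratio = np.inf if w_pred > 0 else 1.0
        flagged = True
    else:
        overlap = max(0.0, min(r.obs_hi, r.pred_hi) - max(r.obs_lo, r.pred_lo))
        p_overlap = overlap / w_obs
        width_ratio = w_pred / w_obs
    # pi = p_overlap ** width_ratio with the limit convention 0^r = 0, r > 0
    if p_overlap == 0.0:
        pi = 0.0
    else:
        pi = p_overlap**width_ratio
    out = {
        "study_id": r.study_id,
        "contrast": r.contrast,
        "p_overlap": p_overlap,
        "abs_diff": abs(r.obs_est - r.pred_mean),
        "width_ratio": width_ratio,
        "pi": pi,
        "flagged_zero_width": flagged,
    }
    if ref is not None:
        if ref.study_id != r.study_id:
            raise ValueError("reference results must align by study_id")
        w_ref = ref.pred_width
        out["pct_reduction"] = 100.0 * (w_ref - w_pred) / w_ref if w_ref > 0 else np.nan
    return out


def comparison_stats(
    results: list[PredictionResult],
    reference_results: list[PredictionResult] | None = None,
) -> pd.DataFrame:
    """Cross-validation statistics per contrast and overall.

    Per study: p_overlap (fraction of the observed CI covered by the
    predicted CrI), |m_obs - m_pred|, w_pred/w_obs, pi = p_overlap **
    (w_pred/w_obs), and, when a reference model's predictions are given,
    the percentage reduction in predicted-interval width vs. that
    reference.  Contrast-level and "All" rows are arithmetic means of the
    per-study values (never ratios of averages).
    """
    if not results:
        raise ValueError("no prediction results to score")
    ref_by_id = (
        {r.study_id: r for r in reference_results}
        if reference_results is not None
        else None
    )
    rows = []
    for r in results:
        ref = None
        if ref_by_id is not None:
            if r.study_id not in ref_by_id:
                raise ValueError(
                    f"reference results missing study {r.study_id!r}"
                )
            ref = ref_by_id[r.study_id]
        rows.append(_study_stats(r, ref))
    per_study = pd.DataFrame(rows)
    cols = ["p_overlap", "abs_diff", "width_ratio", "pi"]
    if "pct_reduction" in per_study.columns:
        cols.append("pct_reduction")
    grouped = per_study.groupby("contrast")[cols].mean()
    overall = per_study[cols].mean().to_frame().T
    overall.index = pd.Index(["All"], name="contrast")
    table = pd.concat([grouped, overall])
    table.attrs["per_study"] = per_study
    return table
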