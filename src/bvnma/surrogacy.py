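"""Study-level and treatment-level surrogacy criteria from posterior draws.

A perfect study-level surrogate within contrast kl has between-study
correlation rho_1kl,2kl = +/-1 and a zero implied intercept
lambda0 = d_2kl - d_1kl rho tau2/tau1 (a zero mean effect on the surrogate
implies a zero mean effect on the final outcome).  Models with an
exchangeable treatment layer additionally report the treatment-level
correlation rho_t.  No hard "validated surrogate" verdict is emitted;
conventional thresholds are reported as optional flags only, since the
decision should rest on predictions rather than a correlation cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws


def implied_intercept(d1, d2, rho, tau1, tau2):
    """Intercept of the within-contrast surrogate relationship.

    lambda0 = d2 - d1 * rho * tau2 / tau1.  Vectorised; not evaluable
    where tau1 == 0 (returns NaN there).
    """
    d1 = np.asarray(d1, dtype=float)
    tau1 = np.asarray(tau1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = d2 - d1 * rho * np.asarray(tau2, dtype=float) / tau1
    return np.where(tau1 > 0, out, np.nan)


@dataclass(frozen=True)
class SurrogacyReport:
    """Tables of correlations and implied intercepts.

    ``correlations``: one row per contrast (or a single common row for the
    homogeneous-covariance variants and BRMA), plus a treatment-level row
    for the exchangeable variants.  ``intercepts``: per-contrast implied
    intercepts (the homogeneous variants still give per-contrast values,
    combining contrast-specific means with the common (rho, tau)).
    """

    variant: str
    correlations: pd.DataFrame
    intercepts: pd.DataFrame

    def to_text(self) -> str:
        lines = [f"model {self.variant}", "between-study correlations"]
        lines.append(self.correlations.to_string())
        lines.append("implied intercepts")
        lines.append(self.intercepts.to_string())
        return "\n".join(lines)


def _summary_row(x: np.ndarray) -> dict:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"mean": np.nan, "q2_5": np.nan, "q97_5": np.nan}
    q = np.percentile(x, [2.5, 97.5])
    return {"mean": float(x.mean()), "q2_5": float(q[0]), "q97_5": float(q[1])}


def surrogacy_report(
    draws: PosteriorDraws,
    rho_extreme_margin: float = 0.15,
) -> SurrogacyReport:
    """Summarise surrogacy parameters from a fitted model.

    Correlation rows carry a flag ``near_extreme`` (whole 95% CrI within
    ``rho_extreme_margin`` of +/-1) and intercept rows a flag
    ``cri_excludes_zero``.  Intercepts are computed per posterior draw
    (never by plugging in posterior means).  For models without a
    treatment-level layer the rho_t entry is simply absent.
    """
    model = draws.model
    variant = model.variant
    per_contrast_rho = model.cov_structure in ("free", "ancillary", "ancillary_hier")

    corr_rows = []
    if per_contrast_rho:
        for k, l in model.contrasts:
            lab = f"{k}{l}"
            rho = draws.flat(f"rho[{lab}]")
            row = {"level": "contrast", "name": lab, **_summary_row(rho)}
            row["near_extreme"] = bool(
                row["q2_5"] >= 1.0 - rho_extreme_margin
                or row["q97_5"] <= -1.0 + rho_extreme_margin
            )
            corr_rows.append(row)
    else:
        rho = draws.flat("rho")
        row = {"level": "common", "name": "all", **_summary_row(rho)}
        row["near_extreme"] = bool(
            row["q2_5"] >= 1.0 - rho_extreme_margin
            or row["q97_5"] <= -1.0 + rho_extreme_margin
        )
        corr_rows.append(row)
    if model.mean_structure == "exchangeable":
        rt = draws.flat("rho_t")
        row = {"level": "treatment", "name": "rho_t", **_summary_row(rt)}
        row["near_extreme"] = bool(
            row["q2_5"] >= 1.0 - rho_extreme_margin
            or row["q97_5"] <= -1.0 + rho_extreme_margin
        )
        corr_rows.append(row)

    int_rows = []
    for k, l in model.contrasts:
        lab = f"{k}{l}"
        d1 = draws.flat(f"d1[{lab}]")
        d2 = draws.flat(f"d2[{lab}]")
        if per_contrast_rho:
            rho = draws.flat(f"rho[{lab}]")
            tau1 = draws.flat(f"tau1[{lab}]")
            tau2 = draws.flat(f"tau2[{lab}]")
        else:
            rho = draws.flat("rho")
            tau1 = draws.flat("tau1")
            tau2 = draws.flat("tau2")
        lam = implied_intercept(d1, d2, rho, tau1, tau2)
        n_bad = int(np.sum(~np.isfinite(lam)))
        row = {"level": "contrast", "name": lab, **_summary_row(lam)}
        row["cri_excludes_zero"] = bool(
            (row["q2_5"] > 0 or row["q97_5"] < 0)
            if np.isfinite(row["q2_5"])
            else False
        )
        row["n_not_evaluable"] = n_bad
        int_rows.append(row)

    return SurrogacyReport(
        variant=variant,
        correlations=pd.DataFrame(corr_rows),
        intercepts=pd.DataFrame(int_rows),
    )
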