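"""Dose-response models for clonogenic survival: linear vs linear-quadratic.

Survival fractions from colony counts are fitted against absorbed dose with

    SF(D) = exp(-alpha D - beta D^2)

by nonlinear least squares on the survival fraction itself (unweighted, with
a log-domain option), with alpha, beta >= 0.  Model choice between the linear
special case (beta = 0) and the full LQ form uses the Akaike information
criterion AIC = n ln(RSS/n) + 2k; ties go to the model with fewer
parameters.  A fitted alpha/beta above 100 Gy is reported as the linear
regime.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SurvivalDataset",
    "DoseResponseFit",
    "survival_from_colonies",
    "fit_dose_response",
    "model_select_aic",
]

LINEAR_REGIME_ALPHA_BETA_GY = 100.0


class ResponseError(ValueError):
    pass


@dataclass
class SurvivalDataset:
    """Survival fractions vs absorbed dose for one exposure."""

    doses_gy: np.ndarray
    survival: np.ndarray
    dose_sd: np.ndarray | None = None
    sem: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.doses_gy = np.asarray(self.doses_gy, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(self.doses_gy < 0):
            raise ResponseError("doses must be >= 0")
        if np.any(self.survival <= 0) or np.any(self.survival > 1.0 + 1e-9):
            raise ResponseError("survival fractions must lie in (0, 1]")


@dataclass
class DoseResponseFit:
    model: str  # "linear" or "LQ"
    alpha: float
    alpha_sd: float
    beta: float
    beta_sd: float
    r2: float
    r2_log: float
    aic: float
    n_points: int
    label: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def alpha_beta_gy(self) -> float:
        return np.inf if self.beta == 0 else self.alpha / self.beta

    @property
    def linear_regime(self) -> bool:
        return self.alpha_beta_gy > LINEAR_REGIME_ALPHA_BETA_GY


def survival_from_colonies(
    colonies: np.ndarray,
    cells_seeded: np.ndarray | float,
    plating_efficiency: float,
) -> tuple[np.ndarray, float]:
    """Survival fraction per replicate and the SEM across replicates.

    SF = (colonies / seeded) / PE.  Zero-colony replicates give SF = 0 and
    should be excluded from log-domain fitting by the caller.
    """
    colonies = np.asarray(colonies, dtype=float)
    seeded = np.asarray(cells_seeded, dtype=float)
    if np.any(colonies < 0):
        raise ResponseError("colony counts must be >= 0")
    if not 0 < plating_efficiency <= 1:
        raise ResponseError("plating efficiency must be in (0, 1]")
    if np.any(seeded <= 0):
        raise ResponseError("zero cells seeded")
    sf = colonies / seeded / plating_efficiency
    sem = float(np.std(sf, ddof=1) / np.sqrt(sf.size)) if sf.size > 1 else 0.0
    return sf, sem


def _r_squared(y, pred):
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_dose_response(
    data: SurvivalDataset, model: str = "LQ", log_domain: bool = False
) -> DoseResponseFit:
    """Least-squares fit of SF = exp(-alpha D - beta D^2), alpha,beta >= 0.

    ``model`` is "linear" (beta fixed at 0) or "LQ".  By default residuals
    are taken on SF; ``log_domain=True`` fits ln SF instead.  R^2 is reported
    on both scales (``r2`` on SF, ``r2_log`` on ln SF) since the convention
    for nonlinear fits is ambiguous.
    """
    if model not in ("linear", "LQ"):
        raise ResponseError(f"unknown model {model!r}")
    k = 1 if model == "linear" else 2
    d, sf = data.doses_gy, data.survival
    if d.size < k + 1:
        raise ResponseError(f"need at least {k + 1} dose points for the {model} model")

    y = np.log(sf) if log_domain else sf

    if model == "linear":

        def f(dd, alpha):
            val = -alpha * dd
            return val if log_domain else np.exp(val)

        p0, bounds = [0.3], ([0.0], [np.inf])
    else:

        def f(dd, alpha, beta):
            val = -alpha * dd - beta * dd**2
            return val if log_domain else np.exp(val)

        p0, bounds = [0.3, 0.05], ([0.0, 0.0], [np.inf, np.inf])

    try:
        popt, pcov = curve_fit(f, d, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise ResponseError(f"dose-response fit failed to converge: {exc}") from exc
    sds = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(k, np.nan)

    alpha = float(popt[0])
    beta = float(popt[1]) if k == 2 else 0.0
    pred_sf = np.exp(-alpha * d - beta * d**2)
    rss = float(np.sum(((np.log(pred_sf) if log_domain else pred_sf) - y) ** 2))
    n = d.size
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return DoseResponseFit(
        model=model,
        alpha=alpha,
        alpha_sd=float(sds[0]),
        beta=beta,
        beta_sd=float(sds[1]) if k == 2 else 0.0,
        r2=_r_squared(sf, pred_sf),
        r2_log=_r_squared(np.log(sf), np.log(pred_sf)),
        aic=float(aic),
        n_points=n,
        label=data.label,
        meta={"log_domain": log_domain},
    )


def model_select_aic(fits: list[DoseResponseFit]) -> DoseResponseFit:
    """Choose the minimum-AIC fit; ties go to fewer parameters.

    The chosen fit's ``meta`` records the AIC differences and whether the
    response is in the linear regime (linear model chosen, or fitted
    alpha/beta above 100 Gy).
    """
    if not fits:
        raise ResponseError("no fits to select from")
    n_params = {"linear": 1, "LQ": 2}
    order = sorted(fits, key=lambda f: (round(f.aic, 9), n_params[f.model]))
    best = order[0]
    best.meta["delta_aic"] = {f.model: f.aic - best.aic for f in fits}
    best.meta["tie"] = len(fits) > 1 and abs(order[0].aic - order[1].aic) < 1e-9
    best.meta["linear_regime"] = best.model == "linear" or best.linear_regime
    return best
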