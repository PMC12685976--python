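"""Cumulative-link mixed model with crossed random intercepts.

Fits, by maximum marginal likelihood with a Laplace approximation, the
ordinal regression model

    P(y_n <= k) = logistic(c_k - u_{item(n)} - v_{part(n)}),
    u_i ~ N(0, sigma_item^2),   v_p ~ N(0, sigma_part^2),

with ordered cutpoints c_1 < ... < c_{K-1} and independent crossed
Gaussian random intercepts for items and participants.  The conditional
modes of the item effects u_i are the "latent means": per-item location
estimates on the logit scale, corrected for participant response bias.

The marginal likelihood integrates over all q = I + P latent effects; the
Laplace approximation replaces the integral with the penalised
log-likelihood at its joint mode b-hat plus a curvature correction,

    log L  ~=  l_pen(b-hat) + (q/2) log 2*pi - (1/2) log det H(b-hat),

where H is the negative Hessian of the penalised log-likelihood.  The
inner mode-finding problem is strictly concave (ordered-logit
log-likelihood is concave in the linear predictor; the Gaussian penalty
adds positive curvature), so a damped Newton iteration converges
reliably; the outer problem over (cutpoints, log sigmas) is solved with
L-BFGS-B and finite-difference gradients.  Fits are deterministic for
fixed data and optimizer settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimisation fails."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CLMMFit:
    """Result of a crossed random-intercepts cumulative-logit fit.

    ``item_effects`` and ``participant_effects`` are the conditional modes
    of the random intercepts, centred to mean zero (the common offset is
    absorbed by the cutpoints and is not identified separately).
    """

    cutpoints: np.ndarray
    sigma_item: float
    sigma_participant: float
    item_effects: pd.Series
    participant_effects: pd.Series
    loglik: float
    n_obs: int
    converged: bool
    diagnostics: dict

    @property
    def latent_means(self) -> pd.Series:
        """Per-item latent location on the logit link scale."""
        return self.item_effects


def _ordinal_eta_derivs(y, eta, cutpoints):
    """Log-likelihood, gradient and curvature w.r.t. the linear predictor.

    y is 0-based category codes; eta the per-observation linear predictor
    (theta-like term entering with a minus sign inside the logistic).
    Returns (loglik_total, g, w) with g = d l_n / d eta and
    w = -d^2 l_n / d eta^2 >= 0.
    """
    c_ext = np.concatenate(([-np.inf], cutpoints, [np.inf]))
    a_hi = c_ext[y + 1] - eta
    a_lo = c_ext[y] - eta
    F_hi = expit(a_hi)
    F_lo = expit(a_lo)
    P = np.clip(F_hi - F_lo, 1e-300, None)
    f_hi = F_hi * (1.0 - F_hi)
    f_lo = F_lo * (1.0 - F_lo)
    Pp = f_lo - f_hi  # dP/d eta
    fp_hi = f_hi * (1.0 - 2.0 * F_hi)
    fp_lo = f_lo * (1.0 - 2.0 * F_lo)
    Ppp = fp_hi - fp_lo  # d2P/d eta2
    g = Pp / P
    w = g * g - Ppp / P
    return float(np.log(P).sum()), g, np.maximum(w, 0.0)


class _LaplaceObjective:
    """Penalised-mode finder and Laplace marginal log-likelihood."""

    def __init__(self, y, item_idx, part_idx, n_items, n_parts, n_levels):
        self.y = y
        self.item_idx = item_idx
        self.part_idx = part_idx
        self.I = n_items
        self.P = n_parts
        self.K = n_levels
        self.n = y.size
        self.b = np.zeros(n_items + n_parts)  # warm-started across calls

    def _penalised(self, b, cutpoints, var_i, var_p):
        u = b[: self.I]
        v = b[self.I:]
        eta = u[self.item_idx] + v[self.part_idx]
        ll, g, w = _ordinal_eta_derivs(self.y, eta, cutpoints)
        pen = (
            -0.5 * (u @ u) / var_i
            - 0.5 * (v @ v) / var_p
            - 0.5 * self.I * (np.log(var_i) + _LOG_2PI)
            - 0.5 * self.P * (np.log(var_p) + _LOG_2PI)
        )
        return ll + pen, g, w

    def _newton(self, cutpoints, var_i, var_p, tol=1e-9, max_iter=60):
        b = self.b.copy()
        obj, g, w = self._penalised(b, cutpoints, var_i, var_p)
        for _ in range(max_iter):
            grad = np.empty_like(b)
            grad[: self.I] = (
                np.bincount(self.item_idx, weights=g, minlength=self.I)
                - b[: self.I] / var_i
            )
            grad[self.I:] = (
                np.bincount(self.part_idx, weights=g, minlength=self.P)
                - b[self.I:] / var_p
            )
            H = self._neg_hessian(w, var_i, var_p)
            c, low = cho_factor(H, check_finite=False)
            step = cho_solve((c, low), grad, check_finite=False)
            t = 1.0
            for _ in range(40):
                b_new = b + t * step
                obj_new, g_new, w_new = self._penalised(
                    b_new, cutpoints, var_i, var_p
                )
                if obj_new >= obj - 1e-12:
                    break
                t *= 0.5
            improved = obj_new - obj
            b, obj, g, w = b_new, obj_new, g_new, w_new
            if np.max(np.abs(grad)) < tol and improved < 1e-10:
                break
        self.b = b
        return b, obj, w

    def _neg_hessian(self, w, var_i, var_p):
        H = np.zeros((self.I + self.P, self.I + self.P))
        np.fill_diagonal(
            H[: self.I, : self.I],
            np.bincount(self.item_idx, weights=w, minlength=self.I)
            + 1.0 / var_i,
        )
        np.fill_diagonal(
            H[self.I:, self.I:],
            np.bincount(self.part_idx, weights=w, minlength=self.P)
            + 1.0 / var_p,
        )
        cross = np.zeros((self.I, self.P))
        np.add.at(cross, (self.item_idx, self.part_idx), w)
        H[: self.I, self.I:] = cross
        H[self.I:, : self.I] = cross.T
        return H

    def laplace_loglik(self, params) -> float:
        """Laplace-approximated marginal log-likelihood at packed params.

        params = [c_1, log(c_2-c_1), ..., log(c_{K-1}-c_{K-2}),
                  log sigma_item, log sigma_part].
        """
        cutpoints = _unpack_cutpoints(params, self.K)
        var_i = np.exp(2.0 * params[-2])
        var_p = np.exp(2.0 * params[-1])
        _, obj, w = self._newton(cutpoints, var_i, var_p)
        H = self._neg_hessian(w, var_i, var_p)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        q = self.I + self.P
        return obj + 0.5 * q * _LOG_2PI - 0.5 * logdet


def _unpack_cutpoints(params, n_levels):
    c = np.empty(n_levels - 1)
    c[0] = params[0]
    c[1:] = params[0] + np.cumsum(np.exp(params[1 : n_levels - 1]))
    return c


def _initial_params(y, n_levels):
    counts = np.bincount(y, minlength=n_levels).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-3, 1.0 - 1e-3)
    c0 = np.log(cum / (1.0 - cum))
    c0 = np.maximum.accumulate(c0)
    diffs = np.clip(np.diff(c0), 1e-2, None)
    return np.concatenate(
        ([c0[0]], np.log(diffs), [np.log(0.5), np.log(0.5)])
    )


def fit_clmm(
    values,
    item_ids,
    participant_ids,
    n_levels: int = 7,
    value_offset: int = 3,
    maxiter: int = 200,
) -> CLMMFit:
    """Fit the crossed random-intercepts cumulative-logit model.

    Parameters
    ----------
    values
        Observed ordinal responses, integers in [-value_offset,
        n_levels - 1 - value_offset] (default: the -3..3 Likert coding).
    item_ids, participant_ids
        Grouping labels, one per observation.
    n_levels
        Number of scale points (cutpoints fitted: n_levels - 1).

    Returns a :class:`CLMMFit` whose ``item_effects`` are the latent means.
    """
    values = np.asarray(values)
    y = (values + value_offset).astype(np.int64)
    if y.min() < 0 or y.max() >= n_levels:
        raise ValueError("responses outside the declared scale range")
    item_cat = pd.Categorical(np.asarray(item_ids, dtype=object))
    part_cat = pd.Categorical(np.asarray(participant_ids, dtype=object))
    n_items = len(item_cat.categories)
    n_parts = len(part_cat.categories)
    if n_items < 2 or n_parts < 2:
        raise ValueError("need at least 2 items and 2 participants")
    if np.unique(y).size < 2:
        raise ValueError(
            "only one response level observed; cutpoints are unidentifiable"
        )

    obj = _LaplaceObjective(
        y, item_cat.codes.astype(np.int64), part_cat.codes.astype(np.int64),
        n_items, n_parts, n_levels,
    )
    x0 = _initial_params(y, n_levels)
    bounds = (
        [(-20.0, 20.0)]
        + [(-8.0, 5.0)] * (n_levels - 2)
        + [(-4.0, 3.0), (-4.0, 3.0)]
    )
    res = optimize.minimize(
        lambda p: -obj.laplace_loglik(p),
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
    )
    diagnostics = {
        "message": str(res.message),
        "n_outer_iterations": int(res.nit),
        "projected_gradient_max": float(np.max(np.abs(res.jac))),
        "n_function_evaluations": int(res.nfev),
    }
    if not np.isfinite(res.fun):
        raise ConvergenceError(
            "marginal likelihood diverged", diagnostics
        )
    if not res.success and diagnostics["projected_gradient_max"] > 1e-2:
        raise ConvergenceError(
            f"CLMM did not converge: {res.message}", diagnostics
        )

    cutpoints = _unpack_cutpoints(res.x, n_levels)
    var_i = np.exp(2.0 * res.x[-2])
    var_p = np.exp(2.0 * res.x[-1])
    b, _, _ = obj._newton(cutpoints, var_i, var_p, tol=1e-10)
    u = b[:n_items]
    v = b[n_items:]
    # centre both effect sets; the common offset belongs to the cutpoints
    item_effects = pd.Series(
        u - u.mean(), index=list(item_cat.categories), name="latent_mean"
    )
    part_effects = pd.Series(
        v - v.mean(), index=list(part_cat.categories),
        name="participant_effect",
    )
    return CLMMFit(
        cutpoints=cutpoints,
        sigma_item=float(np.sqrt(var_i)),
        sigma_participant=float(np.sqrt(var_p)),
        item_effects=item_effects,
        participant_effects=part_effects,
        loglik=float(-res.fun),
        n_obs=int(y.size),
        converged=bool(res.success),
        diagnostics=diagnostics,
    )
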