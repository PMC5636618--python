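"""Time-to-endpoint analysis: Kaplan-Meier estimation and Weibull AFT fitting.

Time is measured in days from treatment start to the day the tumour reached
the humane-endpoint volume; animals whose tumour never reached it are right
censored (here at day 53).  The product-limit estimator handles ties by
processing events before censorings at equal times.  The Weibull model is the
accelerated failure time parameterisation

    log T = mu + x'beta + sigma * W,   W ~ standard Gumbel (minimum)

so T is Weibull with shape k = 1/sigma and scale exp(mu + x'beta); treatment
coefficients beta are log-time ratios.  The fit is a censored maximum
likelihood with analytic gradient, Newton-polished until the gradient norm
drops below 1e-8; the covariance of the estimates is the inverse observed
information.  Fixing the shape at 1 recovers the exponential model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["SurvivalRecord", "KMEstimate", "WeibullFit", "km_estimate", "weibull_fit"]


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    time_days: float
    event: bool  # True = endpoint reached, False = censored

    def __post_init__(self) -> None:
        if not self.time_days > 0:
            raise ValueError("time must be positive")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival outside [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def survival_at(self, t: float) -> float:
        """S(t), with S(0) = 1 and drops at event times."""
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s

    @property
    def plateau(self) -> float:
        """Survival level after the last event."""
        return self.survival[-1] if self.survival else 1.0

    def restricted_mean(self, t_max: float) -> float:
        """Area under the survival step function from 0 to ``t_max``."""
        area = 0.0
        s_prev = 1.0
        t_prev = 0.0
        for et, sv in zip(self.event_times, self.survival):
            if et >= t_max:
                break
            area += s_prev * (et - t_prev)
            s_prev, t_prev = sv, et
        area += s_prev * (t_max - t_prev)
        return area

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (inf if never reached)."""
        for et, sv in zip(self.event_times, self.survival):
            if sv <= 0.5:
                return et
        return float("inf")


def km_estimate(records) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with right censoring.

    At each distinct event time t: S -> S * (1 - d_t / n_t) where d_t is the
    number of events and n_t the number at risk just before t; censorings at t
    remain at risk for the drop at t (events processed before censorings).
    Invariant to the order of the input records.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one record")
    times = np.array([r.time_days for r in recs])
    events = np.array([bool(r.event) for r in recs])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    out_t, out_n, out_d, out_s = [], [], [], []
    s = 1.0
    n_at_risk = len(times)
    for t in np.unique(times):
        at_t = times == t
        d = int(np.sum(events[at_t]))
        c = int(np.sum(~events[at_t]))
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out_t.append(float(t))
            out_n.append(n_at_risk)
            out_d.append(d)
            out_s.append(s)
        n_at_risk -= d + c
    return KMEstimate(tuple(out_t), tuple(out_n), tuple(out_d), tuple(out_s))


# ---------------------------------------------------------------------------
# Weibull accelerated failure time model
# ---------------------------------------------------------------------------

@dataclass
class WeibullFit:
    shape: float  # k = 1/sigma
    scale_days: float  # exp(mu), baseline scale
    coefficients: dict[str, float]  # log-time effects per non-reference level
    cov: np.ndarray  # covariance of (mu, betas..., log sigma)
    param_names: tuple[str, ...]
    log_likelihood: float
    grad_norm: float
    converged: bool
    n_events: int

    def __post_init__(self) -> None:
        if not self.shape > 0 or not self.scale_days > 0:
            raise ValueError("shape and scale must be positive")

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.cov))
        return dict(zip(self.param_names, se))


def _design(records, treatment):
    t = np.array([r.time_days for r in records], dtype=float)
    d = np.array([bool(r.event) for r in records], dtype=float)
    if treatment is None:
        levels = []
        x = np.zeros((len(t), 0))
    else:
        treatment = list(treatment)
        if len(treatment) != len(t):
            raise ValueError("treatment factor length mismatch")
        seen: list[str] = []
        for lv in treatment:
            if lv not in seen:
                seen.append(lv)
        levels = seen[1:]  # first level of appearance is the reference
        x = np.column_stack([[1.0 if lv == ref else 0.0 for lv in treatment] for ref in levels]) if levels else np.zeros((len(t), 0))
    return t, d, x, levels


def _negll_and_grad(p, logt, d, x, fixed_log_sigma):
    ncov = x.shape[1]
    mu = p[0]
    beta = p[1 : 1 + ncov]
    log_sigma = fixed_log_sigma if fixed_log_sigma is not None else p[1 + ncov]
    sigma = np.exp(log_sigma)
    eta = mu + x @ beta
    z = (logt - eta) / sigma
    ez = np.exp(z)
    ll = np.sum(d * (-log_sigma - logt + z) - ez)
    dl_deta = (-d + ez) / sigma  # d(ll)/d(eta) = -(d - e^z)/sigma
    g = np.empty(len(p))
    g[0] = np.sum(dl_deta)
    if ncov:
        g[1 : 1 + ncov] = x.T @ dl_deta
    if fixed_log_sigma is None:
        g[1 + ncov] = np.sum(-d + (d - ez) * (-z))
    return -ll, -g


def weibull_fit(
    records,
    treatment=None,
    fix_shape: float | None = None,
) -> WeibullFit:
    """Censored MLE of the Weibull AFT model with an optional treatment factor.

    ``treatment`` is a factor level per record; the first level encountered is
    the reference.  ``fix_shape`` constrains the shape (1 = exponential).
    Raises if no event is present (scale unidentifiable).
    """
    t, d, x, levels = _design(records, treatment)
    n_events = int(d.sum())
    if n_events < 1:
        raise ValueError("Weibull fit requires at least one event")
    logt = np.log(t)
    fixed_log_sigma = None if fix_shape is None else -np.log(fix_shape)
    ncov = x.shape[1]
    nparam = 1 + ncov + (0 if fix_shape is not None else 1)
    p0 = np.zeros(nparam)
    p0[0] = float(np.log(np.mean(t)))

    res = optimize.minimize(
        _negll_and_grad,
        p0,
        args=(logt, d, x, fixed_log_sigma),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 500},
    )
    p = res.x

    def grad_at(q):
        return _negll_and_grad(q, logt, d, x, fixed_log_sigma)[1]

    def hess_at(q):
        eps = 1e-6 * np.maximum(1.0, np.abs(q))
        h = np.empty((len(q), len(q)))
        for j in range(len(q)):
            dq = np.zeros_like(q)
            dq[j] = eps[j]
            h[:, j] = (grad_at(q + dq) - grad_at(q - dq)) / (2 * eps[j])
        return 0.5 * (h + h.T)

    # Newton polish to push the gradient norm below the convergence criterion
    for _ in range(50):
        g = grad_at(p)
        if np.linalg.norm(g) < 1e-10:
            break
        h = hess_at(p)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        f0 = _negll_and_grad(p, logt, d, x, fixed_log_sigma)[0]
        alpha = 1.0
        for _ in range(30):
            cand = p - alpha * step
            if _negll_and_grad(cand, logt, d, x, fixed_log_sigma)[0] <= f0 + 1e-12:
                p = cand
                break
            alpha *= 0.5
        else:
            break

    negll, neg_g = _negll_and_grad(p, logt, d, x, fixed_log_sigma)
    grad_norm = float(np.linalg.norm(neg_g))
    h = hess_at(p)
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        cov = np.full((nparam, nparam), np.nan)

    mu = p[0]
    beta = p[1 : 1 + ncov]
    log_sigma = fixed_log_sigma if fixed_log_sigma is not None else p[1 + ncov]
    names = ["intercept"] + [f"treatment[{lv}]" for lv in levels]
    if fix_shape is None:
        names.append("log_sigma")
    return WeibullFit(
        shape=float(np.exp(-log_sigma)),
        scale_days=float(np.exp(mu)),
        coefficients=dict(zip([f"treatment[{lv}]" for lv in levels], map(float, beta))),
        cov=cov,
        param_names=tuple(names),
        log_likelihood=float(-negll),
        grad_norm=grad_norm,
        converged=bool(grad_norm < 1e-8),
        n_events=n_events,
    )
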