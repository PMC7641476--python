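"""Model families: losses and the residual vectors that generate gradients.

Screening and KKT certification only ever need the gradient of the
unpenalized loss with respect to the coefficients, and for every supported
family that gradient factors as ``X^T g`` for a sample-length vector ``g``.
The engine works exclusively through that vector:

* Gaussian     f = 1/(2n) ||y - eta||^2,          g = -(y - eta)/n
* Binomial     f = -1/n sum y log p + (1-y) log(1-p),  g = -(y - p)/n
* Cox          f = -1/m sum over events (eta_i - log sum_{risk set} e^eta),
               g given by the Breslow risk-set formula below.

The user-facing convenience functions ``gaussian_residual`` and
``binomial_residual`` return the familiar un-normalized residuals
(``y - eta`` and ``y - p``); ``gradient_vector`` applies the family's
scaling so that ``grad f = X^T gradient_vector`` holds exactly.

Censoring convention: at this interface ``event=True`` means the failure
was observed and ``event=False`` means the observation is right-censored.
Data sources that code censoring the other way around (e.g. an indicator
that is 0 for failure, 1 for censored) must be inverted at ingestion.
Tied event times use the Breslow approximation: tied failures share the
denominator over their common risk set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateResponseError

VALID_FAMILIES = ("gaussian", "binomial", "cox")


@dataclass(frozen=True)
class FamilySpec:
    """Name and structural requirements of a model family."""

    name: str
    requires_status: bool = False

    def __post_init__(self):
        if self.name not in VALID_FAMILIES:
            raise ValueError(f"unknown family {self.name!r}; expected one of {VALID_FAMILIES}")


GAUSSIAN = FamilySpec("gaussian")
BINOMIAL = FamilySpec("binomial")
COX = FamilySpec("cox", requires_status=True)


def family_spec(name: str) -> FamilySpec:
    return {"gaussian": GAUSSIAN, "binomial": BINOMIAL, "cox": COX}[name]


@dataclass(frozen=True)
class SurvivalResponse:
    """Right-censored survival outcome: positive times, event=True for failures."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=np.float64)
        event = np.asarray(self.event, dtype=bool)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.shape != event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(time <= 0):
            raise ValueError("survival times must be strictly positive")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def __len__(self) -> int:
        return self.time.shape[0]


def gaussian_residual(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Working residual ``y - eta``; the screening statistic is |x^T r| / n."""
    y = np.asarray(y, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have equal length")
    return y - eta


def binomial_residual(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Working residual ``y - p`` with p the logistic transform of eta."""
    y = np.asarray(y, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have equal length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("binomial response must be coded 0/1")
    return y - _sigmoid(eta)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(eta, dtype=np.float64)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# -- Cox partial likelihood ---------------------------------------------


def _cox_risk_terms(response: SurvivalResponse, eta: np.ndarray):
    """Shared machinery for the Breslow-tied partial likelihood.

    Returns (m, log_lik_terms..., per-sample cumulative sums).  Samples are
    processed through an ascending sort of the observed times; for each
    unique failure time t_k the risk-set denominator is S_k = sum of
    exp(eta_j) over time_j >= t_k, and d_k failures share it.
    """
    if response.n_events == 0:
        raise DegenerateResponseError("Cox response has no observed events")
    eta = np.asarray(eta, dtype=np.float64)
    if eta.shape[0] != len(response):
        raise ValueError("eta length must match the response")
    time, event = response.time, response.event

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    # stabilize exp by centering eta (partial likelihood is shift invariant)
    eta_c = eta - eta.max()
    w = np.exp(eta_c)[order]

    # suffix sums: S(i) = sum_{j >= i} w_j  -> risk-set mass at t_sorted[i]
    suffix = np.cumsum(w[::-1])[::-1]

    ev_pos = np.nonzero(e_sorted)[0]
    ev_times = t_sorted[ev_pos]
    # first sorted position of each unique failure time -> its risk set
    uniq_times, first_idx_in_ev = np.unique(ev_times, return_index=True)
    first_pos = np.searchsorted(t_sorted, uniq_times, side="left")
    S_k = suffix[first_pos]                       # risk denominators
    d_k = np.diff(np.append(first_idx_in_ev, ev_pos.size))  # ties per unique time
    return order, t_sorted, e_sorted, w, uniq_times, S_k, d_k, eta_c


def cox_neg_log_partial_likelihood(response: SurvivalResponse, eta: np.ndarray) -> float:
    """Breslow negative log partial likelihood, averaged over the m events."""
    order, t_sorted, e_sorted, w, uniq_times, S_k, d_k, eta_c = _cox_risk_terms(response, eta)
    m = response.n_events
    ev_eta_sum = eta_c[response.event].sum()
    return float(-(ev_eta_sum - np.dot(d_k, np.log(S_k))) / m)


def cox_residual(response: SurvivalResponse, eta: np.ndarray) -> np.ndarray:
    """Gradient-generating vector ``g`` with ``grad_beta f = X^T g`` exactly.

    g_i = (1/m) [ exp(eta_i) * sum_{k: t_k <= y_i} d_k / S_k  -  event_i ].
    """
    order, t_sorted, e_sorted, w, uniq_times, S_k, d_k, eta_c = _cox_risk_terms(response, eta)
    m = response.n_events
    # prefix sums of d_k / S_k over unique failure times, looked up per sample
    cum = np.concatenate([[0.0], np.cumsum(d_k / S_k)])
    pos = np.searchsorted(uniq_times, t_sorted, side="right")
    a_sorted = cum[pos]                          # sum over failure times <= own time
    g_sorted = (w * a_sorted - e_sorted) / m
    g = np.empty_like(g_sorted)
    g[order] = g_sorted
    return g


def cox_hessian_diag(response: SurvivalResponse, eta: np.ndarray) -> np.ndarray:
    """Diagonal of the Breslow partial-likelihood Hessian w.r.t. eta.

    w_i = (1/m) [ exp(eta_i) * sum d_k/S_k  -  exp(2 eta_i) * sum d_k/S_k^2 ],
    the standard diagonal surrogate used by IRLS-style penalized Cox solvers.
    """
    order, t_sorted, e_sorted, w, uniq_times, S_k, d_k, eta_c = _cox_risk_terms(response, eta)
    m = response.n_events
    cum1 = np.concatenate([[0.0], np.cumsum(d_k / S_k)])
    cum2 = np.concatenate([[0.0], np.cumsum(d_k / S_k**2)])
    pos = np.searchsorted(uniq_times, t_sorted, side="right")
    h_sorted = (w * cum1[pos] - w**2 * cum2[pos]) / m
    h = np.empty_like(h_sorted)
    h[order] = h_sorted
    return h


def gradient_vector(family: FamilySpec, response, eta: np.ndarray) -> np.ndarray:
    """The vector g such that ``grad_beta f(beta) = X^T g`` for this family."""
    if family.name == "gaussian":
        return -gaussian_residual(response, eta) / len(eta)
    if family.name == "binomial":
        return -binomial_residual(response, eta) / len(eta)
    return cox_residual(response, eta)


def loss(family: FamilySpec, response, eta: np.ndarray) -> float:
    """The family's normalized convex loss f at linear predictor eta."""
    if family.name == "gaussian":
        r = gaussian_residual(response, eta)
        return float(0.5 * np.dot(r, r) / len(r))
    if family.name == "binomial":
        y = np.asarray(response, dtype=np.float64)
        # -1/n sum [y*eta - log(1 + e^eta)], stable via logaddexp
        return float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    return cox_neg_log_partial_likelihood(response, eta)
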