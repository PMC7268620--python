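"""Bayesian estimation of breeding-attempt fate from nest revisitation.

The movement track around a detected nest is collapsed to a daily
capture-recapture-style record: N_t fixes were recorded on day t of the
attempt, Y_t of them inside the nest buffer. Fate is then inferred from a
two-process hierarchical model, closely related to a Bayesian
Cormack-Jolly-Seber formulation:

    survival (latent):   z_t ~ Bernoulli(z_{t-1} * phi_{t-1}),  z_1 = 1
    observation:         Y_t ~ Binomial(N_t, z_t * p_t)
    logit(phi_t) = beta_phi0 + beta_phi1 * t
    logit(p_t)   = beta_p0   + beta_p1   * t

z_t is the attempt's alive/failed status on day t (death is absorbing),
phi_t the daily survival probability and p_t the per-fix probability of
detecting a nest visit given the attempt is alive; both are shared across
all attempts in the population. Priors on the four betas are Normal with
mean 0 and precision 1e-5 (variance 1e5). Fate is P = Pr(z_T = 1), the
probability the attempt was still alive on the last day T of a complete
breeding cycle; if tagging happened mid-attempt, T is the cycle length
minus the nest's age at tagging. Days without fixes enter as N_t = 0 and
carry no information beyond the survival prior.

Inference: the two-state latent chain is marginalized exactly by the
forward algorithm, so MCMC (adaptive random-walk Metropolis) runs on the
four betas only; latent trajectories are recovered by forward-filtering
backward-sampling (FFBS). `exact_fate_probability` exposes the forward
computation at fixed parameters and doubles as the independent check on
the sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .geo_tracks import Track
from .revisitation import BufferSpec, CandidateSite

__all__ = [
    "VisitHistory",
    "ModelParams",
    "MCMCConfig",
    "SurvivalFit",
    "build_visit_history",
    "exact_fate_probability",
    "fit_survival",
    "classify_fate",
]

_PRIOR_VAR = 1e5  # Normal(0, precision 1e-5) on each beta, logit scale
_PCLIP = 1e-12


@dataclass
class VisitHistory:
    """Daily visit record for one breeding attempt (day 1 = first nest visit)."""

    attempt_id: str
    T: int
    N: np.ndarray  # fixes per day, length T
    Y: np.ndarray  # in-buffer fixes per day, length T
    truncated: bool = False  # track ended before day T

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.int64)
        self.Y = np.asarray(self.Y, dtype=np.int64)
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if len(self.N) != self.T or len(self.Y) != self.T:
            raise ValueError("N and Y must have length T")
        if np.any(self.N < 0) or np.any(self.Y < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.Y > self.N):
            raise ValueError(f"attempt {self.attempt_id}: Y_t > N_t")


@dataclass(frozen=True)
class ModelParams:
    beta_phi0: float
    beta_phi1: float
    beta_p0: float
    beta_p1: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta_phi0, self.beta_phi1, self.beta_p0, self.beta_p1])

    def phi(self, t) -> np.ndarray:
        """Daily survival probability at day(s) t (1-based)."""
        return expit(self.beta_phi0 + self.beta_phi1 * np.asarray(t, dtype=float))

    def p(self, t) -> np.ndarray:
        """Visit-detection probability at day(s) t (1-based)."""
        return expit(self.beta_p0 + self.beta_p1 * np.asarray(t, dtype=float))


PARAM_NAMES = ("beta_phi0", "beta_phi1", "beta_p0", "beta_p1")


@dataclass
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 10_000
    n_burn: int = 2_000
    seed: int = 0
    # chain start; None = crude GLM estimates polished to the posterior mode
    init: tuple[float, float, float, float] | None = None
    latent_draws: int = 1000  # posterior draws used for z / P / smoothing (0 = skip)
    rhat_max: float = 1.05
    ess_min: float = 400.0


@dataclass
class SurvivalFit:
    draws: np.ndarray  # (n_chains, n_keep, 4)
    attempt_ids: list[str]
    T: np.ndarray  # per attempt
    P: np.ndarray  # per attempt Pr(z_T = 1)
    alive_prob: np.ndarray  # (n_attempts, T_max) posterior mean of smoothed Pr(z_t=1); NaN beyond T
    z_samples: np.ndarray | None  # (M, n_attempts, T_max) FFBS draws, uint8
    phi_mean: np.ndarray
    phi_ci: np.ndarray  # (2, T_max) 95% credible band
    p_mean: np.ndarray
    p_ci: np.ndarray
    rhat: dict
    ess: dict
    accept_rate: float
    converged: bool

    @property
    def params_mean(self) -> ModelParams:
        m = self.draws.reshape(-1, 4).mean(axis=0)
        return ModelParams(*m)

    def beta_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        i = PARAM_NAMES.index(name)
        flat = self.draws[:, :, i].ravel()
        lo, hi = np.quantile(flat, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# visit histories

def build_visit_history(
    track: Track,
    nest,
    T_full: int,
    days_elapsed_at_tagging: int = 0,
    buffer: BufferSpec = BufferSpec(40.0),
    tz: str = "UTC",
    attempt_id: str | None = None,
) -> VisitHistory:
    """Collapse a track to the daily (N_t, Y_t) record of one attempt.

    ``nest`` is a :class:`CandidateSite` or an (lon, lat) pair. Day 1 is
    the day of the first fix inside the nest buffer. T is the theoretical
    full-cycle length minus the attempt's age at tagging. If the track
    ends before day T the history is zero-padded and flagged truncated
    (the tag failing before the end of the attempt violates a model
    assumption, so the caller is warned).
    """
    if not (T_full > days_elapsed_at_tagging >= 0):
        raise ValueError("need T_full > days_elapsed_at_tagging >= 0")
    if isinstance(nest, CandidateSite):
        lon, lat = nest.center_lon, nest.center_lat
        default_id = f"{nest.track_id}@{nest.first_day.isoformat()}"
    else:
        lon, lat = nest
        default_id = track.id
    T = int(T_full - days_elapsed_at_tagging)
    d = track.distances_to(lon, lat)
    inside = d <= buffer.radius_r
    if not np.any(inside):
        raise ValueError("no fix of the track falls inside the nest buffer")
    day_ords = track.day_ordinals(tz)
    day1 = int(day_ords[inside].min())
    rel = day_ords - day1  # 0-based day of attempt
    in_window = (rel >= 0) & (rel < T)
    N = np.bincount(rel[in_window], minlength=T)[:T]
    Y = np.bincount(rel[in_window & inside], minlength=T)[:T]
    truncated = int(day_ords.max()) < day1 + T - 1
    if truncated:
        warnings.warn(
            f"attempt {attempt_id or default_id}: track ends before day T={T}; "
            "history truncated (model assumes the tag outlives the attempt)"
        )
    return VisitHistory(attempt_id=attempt_id or default_id, T=T, N=N, Y=Y, truncated=truncated)


def _stack(histories: Sequence[VisitHistory]):
    if len(histories) == 0:
        raise ValueError("need at least one visit history")
    Tvec = np.array([h.T for h in histories])
    Tmax = int(Tvec.max())
    n = len(histories)
    N = np.zeros((n, Tmax), dtype=np.int64)
    Y = np.zeros((n, Tmax), dtype=np.int64)
    for i, h in enumerate(histories):
        N[i, : h.T] = h.N
        Y[i, : h.T] = h.Y
    return N, Y, Tvec, [h.attempt_id for h in histories]


# ---------------------------------------------------------------------------
# forward algorithm (exact marginalization of the latent chain)

def _day_probs(theta: np.ndarray, Tmax: int):
    t = np.arange(1, Tmax + 1, dtype=float)
    phi = np.clip(expit(theta[0] + theta[1] * t), _PCLIP, 1 - _PCLIP)
    p = np.clip(expit(theta[2] + theta[3] * t), _PCLIP, 1 - _PCLIP)
    return phi, p


def _emissions(theta: np.ndarray, N: np.ndarray, Y: np.ndarray):
    _, p = _day_probs(theta, N.shape[1])
    log_ea = Y * np.log(p) + (N - Y) * np.log1p(-p)  # binomial coeff. cancels
    ea = np.exp(np.maximum(log_ea, -500.0))
    ed = (Y == 0).astype(float)
    return ea, ed


def _forward(theta: np.ndarray, N: np.ndarray, Y: np.ndarray):
    """Normalized filtered state probabilities and the log marginal likelihood.

    Returns (fa, fd, loglik) with fa[i, j] = Pr(z_{j+1}=1 | Y_{1:j+1}) for
    attempt i; z_1 is fixed to 1.
    """
    n, Tmax = N.shape
    phi, _ = _day_probs(theta, Tmax)
    ea, ed = _emissions(theta, N, Y)
    fa = np.empty((n, Tmax))
    fd = np.empty((n, Tmax))
    a = ea[:, 0].copy()  # z_1 = 1
    d = np.zeros(n)
    ll = 0.0
    s = a + d
    if np.any(s <= 0):
        return fa, fd, -np.inf
    ll += np.log(s).sum()
    a /= s
    fa[:, 0] = a
    fd[:, 0] = 0.0
    for j in range(1, Tmax):
        a_new = a * phi[j - 1] * ea[:, j]
        d_new = (d + a * (1.0 - phi[j - 1])) * ed[:, j]
        s = a_new + d_new
        if np.any(s <= 0):
            return fa, fd, -np.inf
        ll += np.log(s).sum()
        a = a_new / s
        d = d_new / s
        fa[:, j] = a
        fd[:, j] = d
    return fa, fd, float(ll)


def _smooth(theta: np.ndarray, N: np.ndarray, Y: np.ndarray):
    """Smoothed Pr(z_t = 1 | Y_{1:T}) per attempt and day."""
    n, Tmax = N.shape
    phi, _ = _day_probs(theta, Tmax)
    ea, ed = _emissions(theta, N, Y)
    fa, fd, ll = _forward(theta, N, Y)
    ba = np.ones((n, Tmax))
    bd = np.ones((n, Tmax))
    for j in range(Tmax - 2, -1, -1):
        ba[:, j] = phi[j] * ea[:, j + 1] * ba[:, j + 1] + (1.0 - phi[j]) * ed[:, j + 1] * bd[:, j + 1]
        bd[:, j] = ed[:, j + 1] * bd[:, j + 1]
        s = np.maximum(ba[:, j], bd[:, j])
        s[s == 0] = 1.0
        ba[:, j] /= s
        bd[:, j] /= s
    num = fa * ba
    den = num + fd * bd
    den[den == 0] = 1.0
    return num / den, fa, fd


def _ffbs(theta: np.ndarray, N: np.ndarray, Y: np.ndarray, rng: np.random.Generator):
    """One joint draw of the latent alive/dead paths given parameters."""
    n, Tmax = N.shape
    phi, _ = _day_probs(theta, Tmax)
    fa, fd, _ = _forward(theta, N, Y)
    z = np.zeros((n, Tmax), dtype=np.uint8)
    z[:, Tmax - 1] = rng.random(n) < fa[:, Tmax - 1]
    for j in range(Tmax - 2, -1, -1):
        pa = fa[:, j] * (1.0 - phi[j])
        pd_ = fd[:, j]
        s = pa + pd_
        s[s == 0] = 1.0
        cond_alive = pa / s  # Pr(z_j=1 | z_{j+1}=0, data to j)
        z[:, j] = np.where(z[:, j + 1] == 1, 1, (rng.random(n) < cond_alive).astype(np.uint8))
    return z


def exact_fate_probability(history: VisitHistory, params: ModelParams) -> float:
    """Pr(z_T = 1 | Y, N, beta): exact forward computation, no sampling.

    Serves both as the fate estimate at fixed parameters and as the
    independent oracle for the MCMC-based quantities.
    """
    N, Y, Tvec, _ = _stack([history])
    fa, fd, ll = _forward(params.as_array(), N, Y)
    if not np.isfinite(ll):
        raise ValueError("history has zero likelihood under these parameters")
    return float(fa[0, history.T - 1])


# ---------------------------------------------------------------------------
# MCMC

def _log_posterior(theta: np.ndarray, N: np.ndarray, Y: np.ndarray) -> float:
    _, _, ll = _forward(theta, N, Y)
    return ll - float(np.sum(theta**2)) / (2.0 * _PRIOR_VAR)


def _uncenter(theta_c: np.ndarray, tbar: float) -> np.ndarray:
    """Map internally-centered parameters back to the day-1..T scale."""
    out = np.asarray(theta_c, dtype=float).copy()
    out[..., 0] = theta_c[..., 0] - theta_c[..., 1] * tbar
    out[..., 2] = theta_c[..., 2] - theta_c[..., 3] * tbar
    return out


def _logistic_glm(t: np.ndarray, succ: np.ndarray, fail: np.ndarray) -> tuple[float, float]:
    """Tiny ridge-stabilized logistic fit of success odds on the day covariate."""
    from scipy.optimize import minimize

    def nll(b):
        eta = b[0] + b[1] * t
        return float(np.sum(np.logaddexp(0, -eta) * succ + np.logaddexp(0, eta) * fail)) + 1e-4 * (b @ b)

    res = minimize(nll, np.zeros(2), method="Nelder-Mead", options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-8})
    return float(res.x[0]), float(res.x[1])


def _initial_point(N: np.ndarray, Y: np.ndarray, Tvec: np.ndarray) -> np.ndarray:
    """Crude moment-style start: detection from days known alive (up to each
    attempt's last observed visit), survival from a discrete-hazard view that
    places each unobserved death just after the last visit."""
    n, Tmax = N.shape
    t = np.arange(1, Tmax + 1)
    has_visit = Y > 0
    last_visit = np.where(has_visit.any(axis=1), Tmax - 1 - np.argmax(has_visit[:, ::-1], axis=1), -1)
    p_succ = np.zeros(Tmax)
    p_fail = np.zeros(Tmax)
    h_alive = np.zeros(Tmax)
    h_death = np.zeros(Tmax)
    for i in range(n):
        L = int(last_visit[i])
        if L < 0:
            continue
        p_succ[: L + 1] += Y[i, : L + 1]
        p_fail[: L + 1] += N[i, : L + 1] - Y[i, : L + 1]
        h_alive[:L] += 1  # survived day j+1 -> j+2
        if L + 1 < Tvec[i]:
            h_death[L] += 1
    b_p0, b_p1 = _logistic_glm(t.astype(float), p_succ, p_fail)
    b_f0, b_f1 = _logistic_glm(t.astype(float), h_alive, h_death)
    return np.array([b_f0, b_f1, b_p0, b_p1])


def _map_estimate(N: np.ndarray, Y: np.ndarray, Tvec: np.ndarray) -> np.ndarray:
    """Posterior mode, found from the crude start in centered coordinates."""
    from scipy.optimize import minimize

    tbar = (N.shape[1] + 1) / 2.0
    x0 = _initial_point(N, Y, Tvec)
    x0c = x0.copy()
    x0c[0] += x0[1] * tbar
    x0c[2] += x0[3] * tbar

    def neg_lp(tc):
        return -_log_posterior(_uncenter(tc, tbar), N, Y)

    res = minimize(neg_lp, x0c, method="Nelder-Mead", options={"maxiter": 800, "xatol": 1e-5, "fatol": 1e-7})
    return _uncenter(res.x, tbar)


def _run_chain(N, Y, cfg: MCMCConfig, rng: np.random.Generator, init: np.ndarray):
    """Adaptive random-walk Metropolis on the four betas.

    The day covariate is centered internally (intercepts redefined at the
    mid-attempt day) to decorrelate intercept and slope; draws are mapped
    back before being stored. The proposal uses the scaled empirical
    covariance (Haario-style) with an acceptance-targeted global scale,
    both frozen at the end of burn-in.
    """
    tbar = (N.shape[1] + 1) / 2.0
    theta_c = np.asarray(init, dtype=float).copy()
    theta_c[0] += theta_c[1] * tbar
    theta_c[2] += theta_c[3] * tbar
    theta_c += rng.normal(0.0, 0.3, 4) * np.array([1.0, 1.0 / tbar, 1.0, 1.0 / tbar])

    def lp_of(tc):
        return _log_posterior(_uncenter(tc, tbar), N, Y)

    lp = lp_of(theta_c)
    n_keep = cfg.n_iter - cfg.n_burn
    draws = np.empty((n_keep, 4))
    cov_scale = 2.38**2 / 4.0
    base = np.diag([0.04, 0.04 / tbar**2, 0.04, 0.04 / tbar**2])
    chol = np.linalg.cholesky(base)
    log_s = 0.0
    mean = theta_c.copy()
    m2 = np.zeros((4, 4))
    count = 1
    accepted = 0
    recent_acc = 0
    for it in range(cfg.n_iter):
        prop = theta_c + np.exp(log_s) * (chol @ rng.normal(size=4))
        lp_prop = lp_of(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta_c, lp = prop, lp_prop
            accepted += 1
            recent_acc += 1
        count += 1
        delta = theta_c - mean
        mean += delta / count
        m2 += np.outer(delta, theta_c - mean)
        if it + 1 == cfg.n_burn // 2:
            # restart the moment accumulators: the early transient (far from
            # the mode, pre-adaptation) badly distorts the covariance estimate
            mean = theta_c.copy()
            m2 = np.zeros((4, 4))
            count = 1
        if it < cfg.n_burn and it >= 100 and (it + 1) % 25 == 0:
            try:
                chol = np.linalg.cholesky(cov_scale * m2 / (count - 1) + 1e-9 * np.eye(4))
            except np.linalg.LinAlgError:
                pass
            log_s = float(np.clip(log_s + 0.6 * (recent_acc / 25.0 - 0.28), -3.0, 3.0))
            recent_acc = 0
        if it >= cfg.n_burn:
            draws[it - cfg.n_burn] = _uncenter(theta_c, tbar)
    return draws, accepted / cfg.n_iter


def _diagnostics(draws: np.ndarray):
    import arviz as az

    ds = az.from_dict(posterior={name: draws[:, :, i] for i, name in enumerate(PARAM_NAMES)})
    rhat = {k: float(v) for k, v in az.rhat(ds).to_array().to_series().items()}
    ess = {k: float(v) for k, v in az.ess(ds).to_array().to_series().items()}
    return rhat, ess


def fit_survival(histories: Sequence[VisitHistory], mcmc: MCMCConfig | None = None) -> SurvivalFit:
    """Fit the hierarchical survival/detection model to a set of attempts.

    All attempts share the population-level phi_t and p_t curves; fate
    P = Pr(z_T = 1) is computed per attempt, averaging the exact forward
    probability at each retained posterior draw (Rao-Blackwellized over
    the latent chain). Non-convergence (split-Rhat above the gate or ESS
    below it on any beta) is flagged and warned about, never hidden.
    """
    cfg = mcmc or MCMCConfig()
    N, Y, Tvec, ids = _stack(histories)
    n, Tmax = N.shape

    init = np.asarray(cfg.init, dtype=float) if cfg.init is not None else _map_estimate(N, Y, Tvec)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains + 1)
    chains = []
    acc = []
    for c in range(cfg.n_chains):
        d, a = _run_chain(N, Y, cfg, np.random.default_rng(seeds[c]), init)
        chains.append(d)
        acc.append(a)
    draws = np.stack(chains)  # (n_chains, n_keep, 4)

    rhat, ess = _diagnostics(draws)
    converged = all(v <= cfg.rhat_max for v in rhat.values()) and all(v >= cfg.ess_min for v in ess.values())
    if not converged:
        warnings.warn(f"MCMC convergence gate failed: rhat={rhat}, ess={ess}")

    flat = draws.reshape(-1, 4)
    t = np.arange(1, Tmax + 1, dtype=float)
    phi_draws = expit(flat[:, [0]] + flat[:, [1]] * t)
    p_draws = expit(flat[:, [2]] + flat[:, [3]] * t)
    phi_ci = np.quantile(phi_draws, [0.025, 0.975], axis=0)
    p_ci = np.quantile(p_draws, [0.025, 0.975], axis=0)

    P = np.zeros(n)
    alive = np.zeros((n, Tmax))
    z_samples = None
    if cfg.latent_draws > 0:
        M = min(cfg.latent_draws, flat.shape[0])
        idx = np.linspace(0, flat.shape[0] - 1, M).astype(int)
        rng = np.random.default_rng(seeds[-1])
        z_samples = np.zeros((M, n, Tmax), dtype=np.uint8)
        for k, i in enumerate(idx):
            theta = flat[i]
            sm, fa, fd = _smooth(theta, N, Y)
            alive += sm
            P += fa[np.arange(n), Tvec - 1]
            z_samples[k] = _ffbs(theta, N, Y, rng)
        alive /= M
        P /= M
        for i in range(n):
            alive[i, Tvec[i]:] = np.nan
    else:
        alive[:] = np.nan
        P[:] = np.nan

    return SurvivalFit(
        draws=draws,
        attempt_ids=list(ids),
        T=Tvec,
        P=P,
        alive_prob=alive,
        z_samples=z_samples,
        phi_mean=phi_draws.mean(axis=0),
        phi_ci=phi_ci,
        p_mean=p_draws.mean(axis=0),
        p_ci=p_ci,
        rhat=rhat,
        ess=ess,
        accept_rate=float(np.mean(acc)),
        converged=converged,
    )


def classify_fate(fit: SurvivalFit, threshold: float = 0.5) -> pd.DataFrame:
    """Per-attempt success/failure call at a probability threshold.

    Success iff P = Pr(z_T = 1) >= threshold. Also reports the last day
    of the attempt on which the smoothed Pr(z_t = 1) was still at or
    above the threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    rows = []
    for i, aid in enumerate(fit.attempt_ids):
        Ti = int(fit.T[i])
        curve = fit.alive_prob[i, :Ti]
        above = np.flatnonzero(curve >= threshold)
        rows.append(
            {
                "attempt_id": aid,
                "T": Ti,
                "P": float(fit.P[i]),
                "fate": "success" if fit.P[i] >= threshold else "failure",
                "last_day_above": int(above[-1] + 1) if len(above) else 0,
            }
        )
    return pd.DataFrame(rows)
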