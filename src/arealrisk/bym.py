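"""The Besag-York-Mollié convolution model for areal counts.

Likelihood and linear predictor:

    y_i | theta_i ~ Poisson(e_i * theta_i),          i = 1..m,
    log theta_i   = alpha0 + x_i' beta + u_i + v_i,

with e_i the expected count (the offset), alpha0 the common log risk,
beta the covariate effects, u an intrinsic CAR (ICAR) spatial field and
v iid N(0, 1/tau_v) heterogeneity.  The ICAR prior is the improper
Gaussian with structure matrix Q0 = D - W made proper by the
per-component sum-to-zero constraint:

    p(u | tau_u) propto tau_u^{rank(Q0)/2} exp(-tau_u/2 * u' Q0 u),

so each area's conditional prior mean is the average of its neighbours
and its conditional precision is tau_u * degree.  Areas with no
neighbour (islands) have u_i fixed at 0 and are informed by covariates
and v only.  alpha0 and beta carry flat priors by default (normal priors
optional); tau_u and tau_v carry Gamma(0.5, 0.0005) hyperpriors, the
long-standing disease-mapping convention.

Sampling is Metropolis-within-Gibbs: a joint adaptive random-walk update
of (alpha0, beta); single-site random-walk updates of u proposed inside
the sum-to-zero subspace (site i moves by delta*(1 - 1/n_c) while every
other member of its component moves by -delta/n_c, so the constraint
holds exactly in every draw and the kernel is invariant for the
constrained model under any intercept prior); vectorized independent
random-walk updates of v; and conjugate Gamma draws of the two
precisions.  Proposal scales adapt toward 20-40% acceptance during
warm-up only and are frozen afterwards.  The default protocol is 10,000
iterations per chain with the first 4,000 discarded as warm-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .graph import AreaGraph, icar_structure
from .smr import AreaData

__all__ = [
    "BymPriors",
    "BymPosterior",
    "log_posterior",
    "car_full_conditional",
    "bym_fit",
    "summarize_coefficients",
    "relative_risk_summary",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BymPriors:
    """Priors for the convolution model.

    ``beta_prior_sd`` / ``alpha0_prior_sd`` of ``None`` mean improper flat
    priors (the default); a float requests a zero-mean normal prior with
    that SD.  The tau priors are Gamma(shape, rate).
    """

    tau_u_prior: tuple[float, float] = (0.5, 0.0005)
    tau_v_prior: tuple[float, float] = (0.5, 0.0005)
    beta_prior_sd: float | None = None
    alpha0_prior_sd: float | None = None

    def __post_init__(self) -> None:
        if min(self.tau_u_prior) <= 0 or min(self.tau_v_prior) <= 0:
            raise ValueError("Gamma prior parameters must be > 0")


@dataclass
class BymPosterior:
    """Post-warmup draws, stored per chain (leading axis = chain)."""

    alpha0_draws: np.ndarray   # (C, S)
    beta_draws: np.ndarray     # (C, S, p)
    u_draws: np.ndarray        # (C, S, m)
    v_draws: np.ndarray        # (C, S, m)
    tau_u_draws: np.ndarray    # (C, S)
    tau_v_draws: np.ndarray    # (C, S)
    theta_draws: np.ndarray    # (C, S, m)
    n_chains: int
    n_iter: int
    n_warmup: int
    acceptance_rates: dict
    area_ids: list[str]
    coef_names: list[str] = field(default_factory=list)

    @property
    def n_draws_per_chain(self) -> int:
        return self.alpha0_draws.shape[1]

    # flattened (all chains pooled) views used for posterior summaries
    @property
    def alpha0(self) -> np.ndarray:
        return self.alpha0_draws.reshape(-1)

    @property
    def beta(self) -> np.ndarray:
        c, s, p = self.beta_draws.shape
        return self.beta_draws.reshape(c * s, p)

    @property
    def theta(self) -> np.ndarray:
        return self.theta_draws.reshape(-1, self.theta_draws.shape[-1])

    @property
    def u(self) -> np.ndarray:
        return self.u_draws.reshape(-1, self.u_draws.shape[-1])

    @property
    def v(self) -> np.ndarray:
        return self.v_draws.reshape(-1, self.v_draws.shape[-1])

    @property
    def tau_u(self) -> np.ndarray:
        return self.tau_u_draws.reshape(-1)

    @property
    def tau_v(self) -> np.ndarray:
        return self.tau_v_draws.reshape(-1)


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    return (
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


def log_posterior(
    state: Mapping,
    data: AreaData,
    graph: AreaGraph,
    priors: BymPriors,
    Xcov: np.ndarray | None = None,
    parts: bool = False,
):
    """Unnormalized log posterior density of a full state.

    ``state`` maps ``alpha0, beta, u, v, tau_u, tau_v`` to values; ``u``
    must satisfy the per-component centering constraint.  Terms:

    * Poisson:   sum_i [ y_i log(e_i theta_i) - e_i theta_i ]   (log y_i!
      dropped as a constant in the parameters),
    * ICAR:      rank(Q0)/2 * log tau_u - tau_u/2 * u' Q0 u,
    * v:         full iid N(0, 1/tau_v) log density,
    * Gamma log priors for the precisions, and normal log priors for
      alpha0/beta when configured (flat priors contribute 0).

    Overflowing theta returns ``-inf`` instead of raising.  With
    ``parts=True`` a dict of the individual terms plus ``total``.
    """
    alpha0 = float(state["alpha0"])
    beta = np.atleast_1d(np.asarray(state["beta"], dtype=float))
    u = np.asarray(state["u"], dtype=float)
    v = np.asarray(state["v"], dtype=float)
    tau_u = float(state["tau_u"])
    tau_v = float(state["tau_v"])
    m = graph.n_areas
    if data.e is None:
        raise ValueError("expected counts not computed")
    eta = alpha0 + u + v
    if Xcov is not None and np.asarray(Xcov).size:
        eta = eta + np.asarray(Xcov, dtype=float) @ beta
    out: dict[str, float] = {}
    if np.any(eta > 700):
        total = -math.inf
        if parts:
            return {"total": total}
        return total
    theta = np.exp(eta)
    out["poisson"] = float(np.sum(data.y * (np.log(data.e) + eta) - data.e * theta))
    q0 = icar_structure(graph)
    rank = m - graph.n_components
    out["icar"] = 0.5 * rank * math.log(tau_u) - 0.5 * tau_u * float(u @ q0 @ u)
    out["heterogeneity"] = float(
        0.5 * m * (math.log(tau_v) - _LOG_2PI) - 0.5 * tau_v * float(v @ v)
    )
    out["tau_priors"] = _gamma_logpdf(tau_u, *priors.tau_u_prior) + _gamma_logpdf(
        tau_v, *priors.tau_v_prior
    )
    coef_prior = 0.0
    if priors.alpha0_prior_sd is not None:
        sd = priors.alpha0_prior_sd
        coef_prior += -0.5 * (_LOG_2PI + 2 * math.log(sd)) - alpha0**2 / (2 * sd**2)
    if priors.beta_prior_sd is not None and beta.size:
        sd = priors.beta_prior_sd
        coef_prior += float(
            np.sum(-0.5 * (_LOG_2PI + 2 * math.log(sd)) - beta**2 / (2 * sd**2))
        )
    out["coef_priors"] = coef_prior
    out["total"] = sum(out.values())
    return out if parts else out["total"]


def car_full_conditional(
    i: int, u: np.ndarray, tau_u: float, graph: AreaGraph
) -> tuple[float, float]:
    """Mean and variance of u_i given its neighbours under the CAR prior.

    mean = average of u over the neighbours of i;
    variance = 1 / (tau_u * degree(i)).
    """
    deg = int(graph.degrees[i])
    if deg == 0:
        raise ValueError(
            f"area {i} ({graph.area_ids[i]}) has no neighbours; "
            "islands are handled by fixing u_i = 0 upstream"
        )
    nbrs = graph.neighbors()[i]
    mean = float(np.mean([u[j] for j in nbrs]))
    return mean, 1.0 / (tau_u * deg)


class _BymSampler:
    """One-chain Metropolis-within-Gibbs kernel (internal).

    Exposed as a class so the Geweke-style joint-distribution test can
    alternate single sweeps with data regeneration.
    """

    def __init__(self, data, Xcov, graph, priors, rng, target_accept=0.3):
        self.y = data.y.astype(float)
        self.e = data.e.astype(float)
        self.graph = graph
        self.priors = priors
        self.rng = rng
        self.m = graph.n_areas
        self.X = (
            np.zeros((self.m, 0))
            if Xcov is None
            else np.atleast_2d(np.asarray(Xcov, dtype=float))
        )
        if self.X.shape[0] != self.m:
            self.X = self.X.T
        self.p = self.X.shape[1]
        self.target_accept = target_accept

        self.nbrs = graph.neighbors()
        self.comps = [c for c in graph.components()]
        self.comp_of = graph.component_labels
        self.comp_size = np.array([len(self.comps[c]) for c in self.comp_of])
        self.rank_q0 = self.m - graph.n_components
        self.degrees = graph.degrees
        self.edge_list = sorted(graph.edges)

        # per-component-centered covariates (zero on islands): the
        # directions along which beta and the spatial field are confounded
        self.X_centered = np.zeros_like(self.X)
        for j in range(self.p):
            xc = self.X[:, j].copy()
            for comp in self.comps:
                if len(comp) > 1:
                    xc[comp] -= xc[comp].mean()
                else:
                    xc[comp] = 0.0
            self.X_centered[:, j] = xc
        ei, ej = (
            (np.array([e[0] for e in self.edge_list]), np.array([e[1] for e in self.edge_list]))
            if self.edge_list
            else (np.array([], dtype=int), np.array([], dtype=int))
        )
        self._edge_i, self._edge_j = ei, ej
        dxt = self.X_centered[ei] - self.X_centered[ej] if self.p else np.zeros((0, 0))
        self._xt_quad = (
            np.einsum("ej,ej->j", dxt, dxt) if self.p else np.zeros(0)
        )  # x̃' Q0 x̃ per covariate
        self._xt_edge_diff = dxt

        # state
        tot_y, tot_e = self.y.sum(), self.e.sum()
        self.alpha0 = math.log(tot_y / tot_e) if tot_y > 0 else 0.0
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.m)
        self.v = np.zeros(self.m)
        self.tau_u = 10.0
        self.tau_v = 10.0

        # adaptation
        self.block_scale = 0.1
        self.u_scales = np.full(self.m, 0.5)
        self.v_scales = np.full(self.m, 0.5)
        self.shift_scales = np.full(1 + self.p, 0.5)
        self.scale_scales = np.full(2, 0.2)  # log-scale steps for u-, v-rescaling
        self.frozen = False
        self._acc = {"block": 0, "u": 0, "v": 0, "shift": 0, "ushift": 0,
                     "scale": 0, "transfer": 0}
        self._try = {"block": 0, "u": 0, "v": 0, "shift": 0, "ushift": 0,
                     "scale": 0, "transfer": 0}
        self._batch_acc = {
            "block": 0.0,
            "u": np.zeros(self.m),
            "v": np.zeros(self.m),
            "shift": np.zeros(1 + self.p),
            "scale": np.zeros(2),
        }
        self._batch_n = 0

        self._refresh_eta()

    # -- helpers ---------------------------------------------------------
    def _refresh_eta(self):
        self.eta = self.alpha0 + self.X @ self.beta + self.u + self.v
        self.mu = self.e * np.exp(self.eta)

    def _pois_delta(self, d_eta):
        # eta above ~700 would overflow exp; the capped value still yields
        # an astronomically negative delta, i.e. certain rejection
        mu_new = self.e * np.exp(np.minimum(self.eta + d_eta, 700.0))
        return float(np.sum(self.y * d_eta - (mu_new - self.mu)))

    def quad_u(self) -> float:
        return sum(
            (self.u[i] - self.u[j]) ** 2 for i, j in self.graph.edges
        )

    def set_state(self, alpha0, beta, u, v, tau_u, tau_v):
        self.alpha0 = float(alpha0)
        self.beta = np.atleast_1d(np.asarray(beta, dtype=float)).copy()
        self.u = np.asarray(u, dtype=float).copy()
        self.v = np.asarray(v, dtype=float).copy()
        self.tau_u = float(tau_u)
        self.tau_v = float(tau_v)
        self._refresh_eta()

    # -- adaptation ------------------------------------------------------
    def freeze(self):
        self.frozen = True

    def _adapt(self):
        if self.frozen:
            raise RuntimeError("proposal adaptation attempted after warm-up")
        n = max(self._batch_n, 1)
        fac = math.exp(
            min(0.5, max(-0.5, self._batch_acc["block"] / n - self.target_accept))
        )
        self.block_scale = min(10.0, max(1e-4, self.block_scale * fac))
        for name, scales in (
            ("u", self.u_scales),
            ("v", self.v_scales),
            ("shift", self.shift_scales),
            ("scale", self.scale_scales),
        ):
            rates = self._batch_acc[name] / n
            fac = np.exp(np.clip(rates - self.target_accept, -0.5, 0.5))
            np.clip(scales * fac, 1e-4, 10.0, out=scales)
        self._batch_acc = {
            "block": 0.0,
            "u": np.zeros(self.m),
            "v": np.zeros(self.m),
            "shift": np.zeros(1 + self.p),
            "scale": np.zeros(2),
        }
        self._batch_n = 0

    # -- one full sweep --------------------------------------------------
    N_COEF_UPDATES = 5  # block+shift repeats per sweep (cheap next to the u loop)

    def sweep(self, adapt: bool = False):
        rng = self.rng
        pr = self.priors

        for _ in range(self.N_COEF_UPDATES):
            self._update_coefficients(rng, pr)
        self._update_u(rng)
        self._update_v(rng, pr)
        self._update_scales(rng, pr)
        self._update_transfers(rng, pr)
        self._update_taus(rng, pr)

        self._batch_n += 1
        if adapt and self._batch_n >= 50:
            self._adapt()

        # kill accumulated floating drift in the constraint (exact invariance
        # holds analytically; this is numerical hygiene only)
        for comp in self.comps:
            if len(comp) > 1:
                self.u[comp] -= self.u[comp].mean()

    def _update_coefficients(self, rng, pr):
        # (1) joint random-walk update of (alpha0, beta)
        step = rng.standard_normal(1 + self.p) * self.block_scale
        d_eta = step[0] + (self.X @ step[1:] if self.p else 0.0)
        log_alpha = self._pois_delta(d_eta)
        if pr.alpha0_prior_sd is not None:
            sd2 = pr.alpha0_prior_sd**2
            log_alpha += (self.alpha0**2 - (self.alpha0 + step[0]) ** 2) / (2 * sd2)
        if pr.beta_prior_sd is not None and self.p:
            sd2 = pr.beta_prior_sd**2
            new_b = self.beta + step[1:]
            log_alpha += float(np.sum(self.beta**2 - new_b**2)) / (2 * sd2)
        self._try["block"] += 1
        if math.log(rng.random()) < log_alpha:
            self.alpha0 += step[0]
            self.beta = self.beta + step[1:]
            self.eta = self.eta + d_eta
            self.mu = self.e * np.exp(self.eta)
            self._acc["block"] += 1
            self._batch_acc["block"] += 1 / self.N_COEF_UPDATES

        # (1b) ancillarity shift moves: trade a constant between one
        # coefficient and v (eta, hence the likelihood, is untouched);
        # this decouples the coefficients from the heterogeneity field
        # and is what lets alpha0/beta mix at the v-prior scale.
        for q in range(1 + self.p):
            s = self.shift_scales[q] * rng.standard_normal()
            xq = 1.0 if q == 0 else self.X[:, q - 1]
            v_new = self.v - s * xq
            log_alpha = -0.5 * self.tau_v * float(v_new @ v_new - self.v @ self.v)
            if q == 0 and pr.alpha0_prior_sd is not None:
                sd2 = pr.alpha0_prior_sd**2
                log_alpha += (self.alpha0**2 - (self.alpha0 + s) ** 2) / (2 * sd2)
            if q > 0 and pr.beta_prior_sd is not None:
                sd2 = pr.beta_prior_sd**2
                b = self.beta[q - 1]
                log_alpha += (b**2 - (b + s) ** 2) / (2 * sd2)
            self._try["shift"] += 1
            if math.log(rng.random()) < log_alpha:
                if q == 0:
                    self.alpha0 += s
                else:
                    self.beta[q - 1] += s
                self.v = v_new
                self._acc["shift"] += 1
                self._batch_acc["shift"][q] += 1 / self.N_COEF_UPDATES

        # (1c) confounding shift moves: trade a constant between one
        # coefficient and the spatial field along the component-centered
        # covariate direction (beta_j += t, u -= t*x̃_j; the constraint
        # is preserved exactly).  Along this fixed direction the ICAR
        # factor is Gaussian in t — exp(-tau_u/2 (quad - 2t·x̃'Q0u +
        # t²·x̃'Q0x̃)) — so t is proposed from exactly that Gaussian
        # (independence proposal; the ICAR terms cancel) and accepted on
        # the Poisson remainder, whose eta change is only the
        # per-component covariate means plus island raw values.  This is
        # the move that decorrelates beta from a spatially smooth
        # covariate.
        for j in range(self.p):
            qxx = self._xt_quad[j]
            if qxx <= 0:
                continue
            xt = self.X_centered[:, j]
            du_edges = self.u[self._edge_i] - self.u[self._edge_j]
            d = float(du_edges @ self._xt_edge_diff[:, j])  # x̃' Q0 u
            mean_t = d / qxx
            sd_t = 1.0 / math.sqrt(self.tau_u * qxx)
            t = mean_t + sd_t * rng.standard_normal()
            d_eta = t * (self.X[:, j] - xt)
            log_alpha = self._pois_delta(d_eta)
            if pr.beta_prior_sd is not None:
                sd2 = pr.beta_prior_sd**2
                b = self.beta[j]
                log_alpha += (b**2 - (b + t) ** 2) / (2 * sd2)
            self._try["ushift"] += 1
            if math.log(rng.random()) < log_alpha:
                self.beta[j] += t
                self.u = self.u - t * xt
                self.eta = self.eta + d_eta
                self.mu = self.e * np.exp(self.eta)
                self._acc["ushift"] += 1

    def _update_u(self, rng):
        # (2) single-site spatial updates inside the sum-to-zero subspace:
        # u_i moves by delta*(1-1/n_c), the rest of its component by -delta/n_c
        z_all = rng.standard_normal(self.m)
        unif = rng.random(self.m)
        sum_y = np.array([self.y[c].sum() for c in self.comps])
        for i in range(self.m):
            n_c = int(self.comp_size[i])
            if n_c < 2:
                continue  # island: u_i stays exactly 0
            comp = self.comps[self.comp_of[i]]
            delta = self.u_scales[i] * z_all[i]
            d_self = delta * (1.0 - 1.0 / n_c)
            d_other = -delta / n_c
            mu_comp = self.mu[comp]
            s_comp = float(mu_comp.sum())
            mu_i = float(self.mu[i])
            ysum = float(sum_y[self.comp_of[i]])
            d_pois = (
                self.y[i] * d_self
                + (ysum - self.y[i]) * d_other
                - (math.expm1(d_other) * (s_comp - mu_i) + math.expm1(d_self) * mu_i)
            )
            nb_sum = float(self.u[self.nbrs[i]].sum()) if self.degrees[i] else 0.0
            d_quad = 2.0 * delta * (self.degrees[i] * self.u[i] - nb_sum) + (
                delta * delta * self.degrees[i]
            )
            log_alpha = d_pois - 0.5 * self.tau_u * d_quad
            self._try["u"] += 1
            if math.log(unif[i]) < log_alpha:
                self.u[comp] += d_other
                self.u[i] += delta  # net effect d_self on site i
                self.eta[comp] += d_other
                self.eta[i] += delta
                self.mu[comp] = self.e[comp] * np.exp(self.eta[comp])
                self._acc["u"] += 1
                self._batch_acc["u"][i] += 1

    def _update_v(self, rng, pr):
        # (3) vectorized independent updates of v (targets factorize)
        dv = self.v_scales * rng.standard_normal(self.m)
        eta_new = self.eta + dv
        mu_new = self.e * np.exp(eta_new)
        log_alpha_v = (
            self.y * dv
            - (mu_new - self.mu)
            - 0.5 * self.tau_v * ((self.v + dv) ** 2 - self.v**2)
        )
        acc = np.log(rng.random(self.m)) < log_alpha_v
        self.v[acc] += dv[acc]
        self.eta[acc] = eta_new[acc]
        self.mu[acc] = mu_new[acc]
        self._try["v"] += self.m
        self._acc["v"] += int(acc.sum())
        self._batch_acc["v"] += acc

    def _log_marg_u(self, quad):
        # log of the tau_u-marginalized ICAR factor (up to constants):
        # integrating tau_u^{a+rank/2-1} e^{-tau_u (b+quad/2)} over tau_u
        a, b = self.priors.tau_u_prior
        return -(a + 0.5 * self.rank_q0) * math.log(b + 0.5 * quad)

    def _log_marg_v(self, vv):
        a, b = self.priors.tau_v_prior
        return -(a + 0.5 * self.m) * math.log(b + 0.5 * vv)

    def _update_scales(self, rng, pr):
        # (3b) joint rescaling of each random-effect field, with the
        # corresponding precision integrated out (it is redrawn from its
        # conjugate conditional at the end of the sweep, making this a
        # valid partially-collapsed step).  A log-scale multiplicative
        # proposal u -> c*u (Jacobian c^rank on the constrained
        # subspace) moves the field magnitude in one step; collapsing
        # tau means a stale precision value cannot veto the move.
        if self.rank_q0 > 0:
            eps = self.scale_scales[0] * rng.standard_normal()
            c = math.exp(eps)
            d_eta = (c - 1.0) * self.u
            quad = self.quad_u()
            log_alpha = (
                self._pois_delta(d_eta)
                + self._log_marg_u(c * c * quad)
                - self._log_marg_u(quad)
                + self.rank_q0 * eps
            )
            self._try["scale"] += 1
            if math.log(rng.random()) < log_alpha:
                self.u = c * self.u
                self.eta = self.eta + d_eta
                self.mu = self.e * np.exp(self.eta)
                self._acc["scale"] += 1
                self._batch_acc["scale"][0] += 1
        eps = self.scale_scales[1] * rng.standard_normal()
        c = math.exp(eps)
        d_eta = (c - 1.0) * self.v
        vv = float(self.v @ self.v)
        log_alpha = (
            self._pois_delta(d_eta)
            + self._log_marg_v(c * c * vv)
            - self._log_marg_v(vv)
            + self.m * eps
        )
        self._try["scale"] += 1
        if math.log(rng.random()) < log_alpha:
            self.v = c * self.v
            self.eta = self.eta + d_eta
            self.mu = self.e * np.exp(self.eta)
            self._acc["scale"] += 1
            self._batch_acc["scale"][1] += 1

    def _center(self, w):
        """Project a vector onto the ICAR subspace: per-component centered,
        exactly zero on islands."""
        out = w.copy()
        for comp in self.comps:
            if len(comp) > 1:
                out[comp] -= out[comp].mean()
            else:
                out[comp] = 0.0
        return out

    def _quad_of(self, w):
        dw = w[self._edge_i] - w[self._edge_j]
        return float(dw @ dw)

    def _update_transfers(self, rng, pr):
        # (3c) full regime swap: the involution
        #   T(u, v) = (center(v), v - center(v) + u)
        # exchanges the two fields' shapes while keeping u + v (hence the
        # likelihood) exactly fixed.  T is self-inverse with |Jacobian| = 1
        # on the constrained state space, so plain MH applies; with the
        # precisions marginalized out this is the move that jumps between
        # u-dominated and v-dominated explanations of the same totals.
        u_new = self._center(self.v)
        v_new = self.v - u_new + self.u
        log_alpha = (
            self._log_marg_u(self._quad_of(u_new)) - self._log_marg_u(self.quad_u())
            + self._log_marg_v(float(v_new @ v_new)) - self._log_marg_v(float(self.v @ self.v))
        )
        self._try["transfer"] += 1
        if math.log(rng.random()) < log_alpha:
            self.u = u_new
            self.v = v_new
            self._acc["transfer"] += 1

    def _update_taus(self, rng, pr):
        # (4) conjugate Gamma draws of the precisions
        a_u, b_u = pr.tau_u_prior
        self.tau_u = rng.gamma(a_u + 0.5 * self.rank_q0, 1.0 / (b_u + 0.5 * self.quad_u()))
        a_v, b_v = pr.tau_v_prior
        self.tau_v = rng.gamma(a_v + 0.5 * self.m, 1.0 / (b_v + 0.5 * float(self.v @ self.v)))

    def draw_y(self):
        """Regenerate data from the current state (joint-distribution tests)."""
        self.y = self.rng.poisson(self.mu).astype(float)


def bym_fit(
    data: AreaData,
    Xcov: np.ndarray | None,
    graph: AreaGraph,
    priors: BymPriors | None = None,
    n_iter: int = 10_000,
    n_warmup: int = 4_000,
    n_chains: int = 3,
    seed: int = 0,
    thin: int = 1,
    coef_names: Sequence[str] | None = None,
) -> BymPosterior:
    """Fit the convolution model by MCMC.

    ``Xcov`` holds the area-level covariates (typically plug-in factor
    scores, optionally plus raw columns); pass ``None`` for an
    intercept-only model.  The default protocol is 10,000 iterations with
    the first 4,000 discarded as warm-up, and 3 chains.  Proposal scales
    adapt during warm-up only; the post-warm-up kernel is fixed.  The
    same seed and chain count reproduce the draws exactly.
    """
    priors = priors or BymPriors()
    if data.e is None:
        raise ValueError("expected counts not computed; run expected_counts first")
    if data.y.sum() == 0:
        raise ValueError("no observed cases; the model is not estimable")
    if not (0 <= n_warmup < n_iter):
        raise ValueError("need 0 <= n_warmup < n_iter")
    if graph.n_areas != data.n_areas:
        raise ValueError("graph and data disagree on the number of areas")
    if Xcov is not None:
        Xcov = np.atleast_2d(np.asarray(Xcov, dtype=float))
        if Xcov.shape[0] != data.n_areas and Xcov.shape[1] == data.n_areas:
            Xcov = Xcov.T
        if Xcov.shape[1] and not np.all(np.isfinite(Xcov)):
            raise ValueError("covariates contain non-finite values")
        for j in range(Xcov.shape[1]):
            if np.ptp(Xcov[:, j]) == 0:
                raise ValueError(
                    f"covariate column {j} is constant; the intercept is separate"
                )
    p = 0 if Xcov is None else Xcov.shape[1]
    if coef_names is None:
        coef_names = [f"beta_{j + 1}" for j in range(p)]

    n_keep = (n_iter - n_warmup) // thin
    C = n_chains
    m = graph.n_areas
    post = BymPosterior(
        alpha0_draws=np.empty((C, n_keep)),
        beta_draws=np.empty((C, n_keep, p)),
        u_draws=np.empty((C, n_keep, m)),
        v_draws=np.empty((C, n_keep, m)),
        tau_u_draws=np.empty((C, n_keep)),
        tau_v_draws=np.empty((C, n_keep)),
        theta_draws=np.empty((C, n_keep, m)),
        n_chains=C,
        n_iter=n_iter,
        n_warmup=n_warmup,
        acceptance_rates={},
        area_ids=list(data.area_ids),
        coef_names=list(coef_names),
    )
    acc_all = []
    for c in range(C):
        rng = substream(seed, f"bym-chain-{c}")
        smp = _BymSampler(data, Xcov, graph, priors, rng)
        # overdispersed chain starts
        smp.alpha0 += 0.2 * rng.standard_normal()
        smp.beta = smp.beta + 0.2 * rng.standard_normal(p)
        smp._refresh_eta()
        kept = 0
        for it in range(n_iter):
            if it == n_warmup:
                smp.freeze()
            smp.sweep(adapt=it < n_warmup)
            if it >= n_warmup and (it - n_warmup) % thin == 0 and kept < n_keep:
                post.alpha0_draws[c, kept] = smp.alpha0
                post.beta_draws[c, kept] = smp.beta
                post.u_draws[c, kept] = smp.u
                post.v_draws[c, kept] = smp.v
                post.tau_u_draws[c, kept] = smp.tau_u
                post.tau_v_draws[c, kept] = smp.tau_v
                post.theta_draws[c, kept] = np.exp(smp.eta)
                kept += 1
        acc_all.append(
            {k: smp._acc[k] / max(smp._try[k], 1) for k in smp._acc}
        )
    post.acceptance_rates = {
        k: float(np.mean([a[k] for a in acc_all])) for k in acc_all[0]
    }
    return post


def summarize_coefficients(
    post: BymPosterior, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Posterior mean, SD and equal-tailed 95% interval per coefficient.

    The intercept row comes first; quantiles use the sort-and-linearly-
    interpolate rule (numpy's default).
    """
    if post.n_draws_per_chain == 0:
        raise ValueError("posterior is empty")
    names = list(names) if names is not None else list(post.coef_names)
    chains = [("intercept", post.alpha0)]
    chains += [(names[j], post.beta[:, j]) for j in range(post.beta.shape[1])]
    rows = []
    for name, draws in chains:
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows.append(
            {
                "name": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                "q2.5": float(lo),
                "q97.5": float(hi),
            }
        )
    return pd.DataFrame(rows)


def relative_risk_summary(
    post: BymPosterior, area_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-area posterior relative-risk summary.

    Columns: posterior mean of theta_i, equal-tailed 95% interval, and the
    exceedance probability P(theta_i > 1) (strict inequality; a chain
    constant at exactly 1 has exceedance 0).
    """
    if post.n_draws_per_chain == 0:
        raise ValueError("posterior is empty")
    area_ids = list(area_ids) if area_ids is not None else list(post.area_ids)
    th = post.theta
    lo, hi = np.quantile(th, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "area_id": area_ids,
            "theta_mean": th.mean(axis=0),
            "q2.5": lo,
            "q97.5": hi,
            "p_exceed_1": (th > 1.0).mean(axis=0),
        }
    )
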