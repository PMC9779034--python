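"""MCMC convergence diagnostics and choropleth export.

Convergence is assessed quantitatively: the split-chain potential scale
reduction factor (R-hat) and an autocorrelation-sum effective sample
size with Geyer's paired truncation.  The exact formulas (documented on
each function) are deliberately plain-textbook so an independent
re-implementation reproduces them to numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChainSet",
    "gelman_rubin",
    "effective_sample_size",
    "write_choropleth_geojson",
]


@dataclass
class ChainSet:
    """Draws arranged as (n_chains, n_draws, n_params)."""

    draws: np.ndarray
    param_names: list[str]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim == 2:
            self.draws = self.draws[:, :, None]
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_draws, n_params)")
        if self.draws.shape[1] < 2:
            raise ValueError("chains must hold at least 2 draws")
        if len(self.param_names) != self.draws.shape[2]:
            raise ValueError("param_names length must match the parameter axis")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def split(self) -> "ChainSet":
        """Split every chain in half (odd last draw dropped)."""
        n = (self.n_draws // 2) * 2
        halves = np.concatenate(
            [self.draws[:, : n // 2, :], self.draws[:, n // 2 : n, :]], axis=0
        )
        return ChainSet(halves, list(self.param_names))

    @classmethod
    def from_bym(cls, post, include_taus: bool = False) -> "ChainSet":
        """Coefficient chains (intercept + betas, optionally the taus)."""
        arrs = [post.alpha0_draws[:, :, None], post.beta_draws]
        names = ["intercept"] + list(post.coef_names)
        if include_taus:
            arrs += [post.tau_u_draws[:, :, None], post.tau_v_draws[:, :, None]]
            names += ["tau_u", "tau_v"]
        return cls(np.concatenate(arrs, axis=2), names)


def gelman_rubin(chains: ChainSet) -> pd.Series:
    """Split-chain potential scale reduction factor per parameter.

    Each of the C chains of length S is split in half, giving M = 2C
    chains of length n = floor(S/2).  With chain means x̄_m, chain
    variances s_m² (ddof=1), W = mean(s_m²) and B = n·var(x̄_m, ddof=1):

        var⁺ = (n-1)/n · W + B/n,     R̂ = sqrt(var⁺ / W).

    Chains with zero total variance report R̂ = 1.  At least two chains
    are required; for a single chain, call ``ChainSet.split()`` yourself
    and pass the halves (split-chain mode).
    """
    if chains.n_chains < 2:
        raise ValueError(
            "R-hat needs at least 2 chains; for one chain use split-chain "
            "mode: gelman_rubin(chains.split())"
        )
    x = chains.split().draws  # (M, n, P)
    n = x.shape[1]
    means = x.mean(axis=1)                    # (M, P)
    svars = x.var(axis=1, ddof=1)             # (M, P)
    w = svars.mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w == 0, 1.0, rhat)
    return pd.Series(rhat, index=chains.param_names, name="rhat")


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance c_t = (1/S) sum_{s} (x_s - x̄)(x_{s+t} - x̄), via FFT."""
    S = x.shape[0]
    xc = x - x.mean(axis=0)
    nfft = 1 << (2 * S - 1).bit_length()
    F = np.fft.rfft(xc, n=nfft, axis=0)
    acov = np.fft.irfft(F * np.conj(F), n=nfft, axis=0)[:S]
    return acov.real / S


def effective_sample_size(chains: ChainSet) -> pd.DataFrame:
    """Autocorrelation-sum ESS with Geyer paired truncation, per parameter.

    For C chains of length S with per-chain biased autocovariances
    ĉ_{t,m} and ddof-1 variances s_m²:

        W      = mean_m s_m²,
        var⁺   = (S-1)/S · W + var_m(x̄_m, ddof=1)   (second term 0 if C=1),
        ρ̂_t    = 1 - (W - mean_m ĉ_{t,m}) / var⁺,
        Γ̂_k    = ρ̂_{2k} + ρ̂_{2k+1},

    summed over the initial positive, monotonically decreasing sequence
    of Γ̂_k; then τ̂ = -1 + 2 ΣΓ̂ and ESS = C·S / τ̂, capped above at C·S
    and below at 1.  A zero-variance (constant) chain reports ESS = C·S
    with its ``zero_variance`` flag set.
    """
    x = chains.draws
    C, S, P = x.shape
    if S < 10:
        raise ValueError("need chains of length >= 10 for the ESS estimator")
    total = C * S
    ess = np.empty(P)
    flags = np.zeros(P, dtype=bool)
    for p in range(P):
        xp = x[:, :, p].T  # (S, C)
        acov = _autocov(xp)  # (S, C)
        svar = xp.var(axis=0, ddof=1)
        w = svar.mean()
        if w == 0:
            ess[p] = total
            flags[p] = True
            continue
        var_plus = (S - 1) / S * w
        if C > 1:
            var_plus += xp.mean(axis=0).var(ddof=1)
        rho = 1.0 - (w - acov.mean(axis=1)) / var_plus
        tau = -1.0
        prev = np.inf
        k = 0
        while 2 * k + 1 < S:
            gamma = rho[2 * k] + rho[2 * k + 1]
            if gamma <= 0:
                break
            gamma = min(gamma, prev)
            tau += 2.0 * gamma
            prev = gamma
            k += 1
        ess[p] = min(total, max(1.0, total / max(tau, 1e-12)))
    return pd.DataFrame(
        {"ess": ess, "zero_variance": flags}, index=chains.param_names
    )


def write_choropleth_geojson(
    polygons,
    values,
    property_name: str,
    id_property: str = "id",
    allow_missing: bool = False,
    out_path=None,
) -> dict:
    """Attach one numeric property per feature for map rendering.

    ``values`` maps area id -> number.  Input geometries are passed
    through untouched; features without a value get ``null`` (only with
    ``allow_missing``, counted in a warning); a value for an unknown id
    is an error.  Returns the new FeatureCollection (also written to
    ``out_path`` if given).
    """
    import warnings

    if isinstance(polygons, (str, Path)):
        polygons = json.loads(Path(polygons).read_text())
    values = dict(values)
    feature_ids = []
    out_features = []
    for k, feat in enumerate(polygons.get("features", [])):
        props = dict(feat.get("properties") or {})
        fid = props.get(id_property, feat.get("id"))
        if fid is None:
            raise ValueError(f"feature {k} has no '{id_property}' property")
        fid = str(fid)
        feature_ids.append(fid)
        if fid in values:
            props[property_name] = float(values[fid])
        elif allow_missing:
            props[property_name] = None
        else:
            raise ValueError(f"no value supplied for area '{fid}'")
        new_feat = dict(feat)
        new_feat["properties"] = props
        out_features.append(new_feat)
    unknown = sorted(set(map(str, values)) - set(feature_ids))
    if unknown:
        raise ValueError(f"value(s) supplied for unknown area id(s): {unknown}")
    n_missing = sum(
        1 for f in out_features if f["properties"][property_name] is None
    )
    if n_missing:
        warnings.warn(
            f"{n_missing} feature(s) lack a '{property_name}' value", stacklevel=2
        )
    out = {k: v for k, v in polygons.items() if k != "features"}
    out["features"] = out_features
    if out_path is not None:
        Path(out_path).write_text(json.dumps(out))
    return out
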