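"""Bayesian linear model with AR(1) errors for annual cardiac measures.

Model, for subject i at annual visit t:

    y_{i,0} ~ N(mu_{i,0}, sigma_y^2)
    y_{i,t} ~ N(mu_{i,t} + beta * (y_{i,t-1} - mu_{i,t-1}), sigma_y^2),  t >= 1
    mu_{i,t} = alpha_t + gamma_loa*loa_{i,t} + gamma_ace*ace_{i,t}
               + delta*age_i0
    loa_{i,t} ~ Bernoulli(eta_loa),  ace_{i,t} ~ Bernoulli(eta_ace)

Priors: independent N(0, 100^2) on each alpha_t, beta, gamma_loa, gamma_ace,
delta and log sigma_y^2; independent Uniform(0, 1) on eta_loa and eta_ace.

Posterior sampling is a blocked Gibbs scheme:

* all location parameters (alpha_0..alpha_T, gamma_loa, gamma_ace, delta)
  jointly, via the conjugate multivariate normal of the quasi-differenced
  regression y_t - beta*y_{t-1} on x_t - beta*x_{t-1};
* beta, conjugate normal given the residuals e_{i,t} = y_{i,t} - mu_{i,t};
* log sigma_y^2 by slice sampling (the normal prior on the log variance is
  non-conjugate);
* eta_loa, eta_ace from their Beta full conditionals;
* missing covariate indicators and internal missing responses as latent
  variables (data augmentation), preserving the stated model under the
  missing-at-random assumption.  Responses missing from a subject's last
  observed visit onward factor out of the observed-data likelihood exactly,
  so they are truncated rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, xlogy

from dmdlv.types import CohortPanel, ModelParams

LOC_EXTRA = ("gamma_loa", "gamma_ace", "delta")


@dataclass(frozen=True)
class PriorSpec:
    """Vague proper priors: N(0, normal_sd^2) on location parameters, beta
    and log sigma^2; Uniform(0,1) on the covariate probabilities."""

    normal_sd: float = 100.0

    def __post_init__(self) -> None:
        if not self.normal_sd > 0:
            raise ValueError(f"normal_sd must be > 0, got {self.normal_sd}")


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iterations: int = 20_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.n_chains < 2:
            raise ValueError("need n_chains >= 2 for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior mean, equal-tailed 95% credible interval and the
    CI-excludes-zero significance flag for one parameter."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    significant: bool
    rhat: float = np.nan


@dataclass
class FitResult:
    summaries: list[PosteriorSummary]
    draws: dict[str, np.ndarray]        # name -> (chains, kept draws)
    alpha_names: list[str]
    converged: bool
    rhat: dict[str, float]
    max_visit_report: int

    def __getitem__(self, name: str) -> PosteriorSummary:
        for s in self.summaries:
            if s.name == name:
                return s
        raise KeyError(name)

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parameter": s.name, "mean": s.mean, "ci_low": s.ci_low,
              "ci_high": s.ci_high, "significant": s.significant,
              "rhat": s.rhat} for s in self.summaries]
        )


# ---------------------------------------------------------------------------
# data preparation

class _PanelData:
    """DMD-group panel flattened to contiguous per-subject visit runs.

    Cells are (subject, visit) pairs with t < L_i, where L_i is the last
    visit with an observed response (trailing missing truncated).  Within a
    run the response may still be missing (internal gap -> latent) and the
    covariate indicators may be missing (-> latent).
    """

    def __init__(self, panel: CohortPanel, response_name: str):
        df = panel.subset(group="dmd", response_name=response_name)
        if df.empty:
            raise ValueError(
                f"panel has no DMD records for response {response_name!r}")
        df = df.sort_values(["subject_id", "visit"]).reset_index(drop=True)

        i_idx, t_idx, y, loa, ace, age = [], [], [], [], [], []
        y_lat, loa_lat, ace_lat = [], [], []
        n_multi = 0
        si = 0
        for _, sub in df.groupby("subject_id", sort=True):
            sub = sub.set_index("visit").sort_index()
            obs = sub.index[sub["value"].notna()]
            if len(obs) == 0:
                continue
            L = int(obs.max()) + 1
            if not set(range(L)) <= set(sub.index):
                missing = sorted(set(range(L)) - set(sub.index))
                raise ValueError(
                    f"subject {sub['subject_id'].iloc[0]!r} lacks rows for "
                    f"visits {missing}; represent skipped visits as rows "
                    "with missing value")
            if len(obs) >= 2:
                n_multi += 1
            a0 = float(sub["age_baseline"].iloc[0])
            for t in range(L):
                row = sub.loc[t]
                i_idx.append(si)
                t_idx.append(t)
                v = row["value"]
                y.append(0.0 if pd.isna(v) else float(v))
                y_lat.append(pd.isna(v))
                for col, store, lat in (("loa", loa, loa_lat),
                                        ("ace", ace, ace_lat)):
                    c = row[col]
                    store.append(0.0 if pd.isna(c) else float(c))
                    lat.append(pd.isna(c))
                age.append(a0)
            si += 1

        if si < 2 or n_multi < 2:
            raise ValueError(
                "longitudinal fit needs >= 2 subjects with >= 2 observed "
                f"visits (got {si} subjects, {n_multi} with >= 2 visits)")

        self.i_idx = np.asarray(i_idx)
        self.t_idx = np.asarray(t_idx)
        self.y0 = np.asarray(y)
        self.y_lat = np.flatnonzero(y_lat)
        self.loa0 = np.asarray(loa)
        self.loa_lat = np.flatnonzero(loa_lat)
        self.ace0 = np.asarray(ace)
        self.ace_lat = np.flatnonzero(ace_lat)
        self.age = np.asarray(age)
        self.n_cells = self.y0.size
        self.n_subjects = si
        self.n_visits = int(self.t_idx.max()) + 1
        self.lag = self.t_idx > 0          # cells with an AR predecessor
        self.lag_rows = np.flatnonzero(self.lag)
        # cell r+1 continues the same subject's run iff t_idx[r+1] > 0
        self.has_next = np.zeros(self.n_cells, dtype=bool)
        self.has_next[:-1] = self.t_idx[1:] > 0


# ---------------------------------------------------------------------------
# Gibbs sampler

def _slice_sample_logvar(u: float, n: int, ssr: float, prior_sd: float,
                         rng: np.random.Generator, w: float = 1.0,
                         max_steps: int = 50) -> float:
    """Slice sample u = log sigma^2 from its full conditional."""

    def logp(v: float) -> float:
        return -0.5 * n * v - 0.5 * ssr * np.exp(-v) - 0.5 * v * v / prior_sd**2

    height = logp(u) + np.log(rng.random())
    lo = u - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) < height:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < height:
            break
        hi += w
    while True:
        prop = rng.uniform(lo, hi)
        if logp(prop) >= height:
            return prop
        if prop < u:
            lo = prop
        else:
            hi = prop


class _GibbsChain:
    def __init__(self, data: _PanelData, priors: PriorSpec,
                 fixed: dict[str, float], rng: np.random.Generator):
        self.d = data
        self.rng = rng
        self.tau2 = priors.normal_sd ** 2
        self.prior_sd = priors.normal_sd
        self.fixed = fixed

        d = data
        V = d.n_visits
        self.V = V
        self.loc_names = [f"alpha_{t}" for t in range(V)] + list(LOC_EXTRA)
        self.p = len(self.loc_names)

        # mutable state
        self.y = d.y0.copy()
        self.loa = d.loa0.copy()
        self.ace = d.ace0.copy()
        self.theta = np.zeros(self.p)
        self.beta = float(fixed.get("beta", 0.0))
        self.sigma2 = float(fixed.get("sigma_y", 1.0)) ** 2
        self.eta = {
            "loa": float(fixed.get("eta_loa", 0.5)),
            "ace": float(fixed.get("eta_ace", 0.5)),
        }
        self.free_loc = np.array(
            [i for i, nm in enumerate(self.loc_names) if nm not in fixed])
        for i, nm in enumerate(self.loc_names):
            if nm in fixed:
                self.theta[i] = fixed[nm]
        self._init_state()

    # -- initialisation: least squares with beta = 0, jittered per chain
    def _init_state(self) -> None:
        d, rng = self.d, self.rng
        for nm, lat, arr in (("loa", d.loa_lat, self.loa),
                             ("ace", d.ace_lat, self.ace)):
            obs = np.delete(arr, lat)
            frac = obs.mean() if obs.size else 0.5
            if f"eta_{nm}" not in self.fixed:
                self.eta[nm] = float(np.clip(frac, 0.05, 0.95))
            arr[lat] = (rng.random(lat.size) < self.eta[nm]).astype(float)

        X = self._design_plain()
        # visit means as starting alphas; ridge for safety
        A = X.T @ X + 1e-6 * np.eye(self.p)
        b = X.T @ self.y
        theta = np.linalg.solve(A, b)
        theta[self.free_loc] += rng.normal(0, 0.1, self.free_loc.size)
        for i, nm in enumerate(self.loc_names):
            if nm in self.fixed:
                theta[i] = self.fixed[nm]
        self.theta = theta
        mu = X @ theta
        self.y[d.y_lat] = mu[d.y_lat]
        if "sigma_y" not in self.fixed:
            resid = self.y - mu
            self.sigma2 = float(max(np.var(resid), 1e-6))
        if "beta" not in self.fixed:
            self.beta = float(np.clip(rng.normal(0, 0.1), -0.9, 0.9))

    def _design_plain(self) -> np.ndarray:
        d = self.d
        X = np.zeros((d.n_cells, self.p))
        X[np.arange(d.n_cells), d.t_idx] = 1.0
        X[:, self.V] = self.loa
        X[:, self.V + 1] = self.ace
        X[:, self.V + 2] = d.age
        return X

    def _mu(self, X: np.ndarray) -> np.ndarray:
        return X @ self.theta

    # -- updates ----------------------------------------------------------
    def _update_locations(self, X: np.ndarray) -> None:
        free = self.free_loc
        if free.size == 0:
            return
        d = self.d
        lr = d.lag_rows
        Xq = X.copy()
        Xq[lr] -= self.beta * X[lr - 1]
        z = self.y.copy()
        z[lr] -= self.beta * self.y[lr - 1]
        fixed_idx = np.setdiff1d(np.arange(self.p), free)
        if fixed_idx.size:
            z = z - Xq[:, fixed_idx] @ self.theta[fixed_idx]
        Xf = Xq[:, free]
        A = Xf.T @ Xf / self.sigma2 + np.eye(free.size) / self.tau2
        b = Xf.T @ z / self.sigma2
        c, low = cho_factor(A, lower=True)
        mean = cho_solve((c, low), b)
        draw = mean + solve_triangular(c, self.rng.standard_normal(free.size),
                                       lower=True, trans="T")
        self.theta[free] = draw

    def _update_beta(self, mu: np.ndarray) -> None:
        if "beta" in self.fixed:
            return
        d = self.d
        e = self.y - mu
        ep, ec = e[d.lag_rows - 1], e[d.lag_rows]
        prec = ep @ ep / self.sigma2 + 1.0 / self.tau2
        mean = (ep @ ec / self.sigma2) / prec
        self.beta = float(self.rng.normal(mean, 1.0 / np.sqrt(prec)))

    def _update_sigma(self, mu: np.ndarray) -> None:
        if "sigma_y" in self.fixed:
            return
        d = self.d
        e = self.y - mu
        resid = e.copy()
        resid[d.lag_rows] -= self.beta * e[d.lag_rows - 1]
        ssr = float(resid @ resid)
        u = _slice_sample_logvar(float(np.log(self.sigma2)), d.n_cells, ssr,
                                 self.prior_sd, self.rng)
        self.sigma2 = float(np.exp(u))

    def _update_eta(self) -> None:
        for nm, arr in (("loa", self.loa), ("ace", self.ace)):
            if f"eta_{nm}" in self.fixed:
                continue
            s = float(arr.sum())
            n = arr.size
            self.eta[nm] = float(self.rng.beta(1.0 + s, 1.0 + n - s))

    def _cell_resid(self, r: int, mu: np.ndarray) -> float:
        e = self.y[r] - mu[r]
        if self.d.t_idx[r] > 0:
            e -= self.beta * (self.y[r - 1] - mu[r - 1])
        return e

    def _impute_covariates(self, mu: np.ndarray) -> None:
        d = self.d
        for nm, arr, lat, col in (("loa", self.loa, d.loa_lat, self.V),
                                  ("ace", self.ace, d.ace_lat, self.V + 1)):
            if lat.size == 0:
                continue
            g = self.theta[col]
            eta = self.eta[nm]
            logit0 = np.log(eta) - np.log1p(-eta) if 0 < eta < 1 else (
                np.inf if eta >= 1 else -np.inf)
            for r in lat:
                old = arr[r]
                # log-likelihood difference (indicator = 1 minus = 0):
                # mu_r shifts by g in the own term and, through the AR mean,
                # in the next cell's term
                e_own = self._cell_resid(r, mu) + g * old   # residual at ind=0
                dll = (e_own - g) ** 2 - e_own ** 2
                if d.has_next[r]:
                    e_nxt = self._cell_resid(r + 1, mu) - self.beta * g * old
                    dll += (e_nxt + self.beta * g) ** 2 - e_nxt ** 2
                logit = logit0 - dll / (2.0 * self.sigma2)
                new = float(self.rng.random() < expit(logit))
                if new != old:
                    arr[r] = new
                    mu[r] += g * (new - old)

    def _impute_latent_y(self, mu: np.ndarray) -> None:
        d = self.d
        for r in d.y_lat:
            m1 = mu[r]
            if d.t_idx[r] > 0:
                m1 += self.beta * (self.y[r - 1] - mu[r - 1])
            if d.has_next[r]:
                c = self.y[r + 1] - mu[r + 1] + self.beta * mu[r]
                denom = 1.0 + self.beta ** 2
                mean = (m1 + self.beta * c) / denom
                var = self.sigma2 / denom
            else:
                mean, var = m1, self.sigma2
            self.y[r] = self.rng.normal(mean, np.sqrt(var))

    def step(self) -> None:
        X = self._design_plain()
        mu = self._mu(X)
        if self.d.loa_lat.size or self.d.ace_lat.size:
            self._impute_covariates(mu)
            X[:, self.V] = self.loa
            X[:, self.V + 1] = self.ace
        if self.d.y_lat.size:
            self._impute_latent_y(mu)
        self._update_locations(X)
        mu = self._mu(X)
        self._update_beta(mu)
        self._update_sigma(mu)
        self._update_eta()

    def state_vector(self) -> np.ndarray:
        return np.concatenate([
            self.theta,
            [self.beta, np.sqrt(self.sigma2), self.eta["loa"], self.eta["ace"]],
        ])


def fit_model(panel: CohortPanel, response_name: str,
              priors: PriorSpec = PriorSpec(),
              mcmc: McmcConfig = McmcConfig(),
              max_visit_report: int = 5,
              fixed: dict[str, float] | None = None) -> FitResult:
    """Fit the AR(1) longitudinal model to the DMD group by Gibbs sampling.

    Missing responses inside a subject's observed span and missing covariate
    indicators are sampled as latent variables.  Visit-intercept summaries
    are reported only through ``max_visit_report`` (default 5) even when
    later visits were fitted; all draws are retained in ``FitResult.draws``.

    ``fixed`` pins named parameters (e.g. ``{"beta": 0.0, "sigma_y": 1.5}``)
    at known values, which is useful for validation against conjugate
    closed forms.

    Convergence is checked with split-R̂; any parameter above 1.05 flags the
    fit as non-converged (a warning, not an exception).
    """
    data = _PanelData(panel, response_name)
    fixed = dict(fixed or {})
    names = ([f"alpha_{t}" for t in range(data.n_visits)] + list(LOC_EXTRA)
             + ["beta", "sigma_y", "eta_loa", "eta_ace"])

    kept = -(-(mcmc.n_iterations - mcmc.n_burnin) // mcmc.thin)
    out = np.empty((mcmc.n_chains, kept, len(names)))
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        chain = _GibbsChain(data, priors, fixed, rng)
        k = 0
        for it in range(mcmc.n_iterations):
            chain.step()
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                out[c, k] = chain.state_vector()
                k += 1

    draws = {nm: out[:, :, j] for j, nm in enumerate(names)}
    rhat = _rhat(draws, fixed)
    converged = all(r < 1.05 for r in rhat.values() if np.isfinite(r))
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= 1.05}
        warnings.warn(f"MCMC did not converge (rhat > 1.05): {bad}",
                      RuntimeWarning, stacklevel=2)

    report = [nm for nm in names
              if not nm.startswith("alpha_")
              or int(nm.split("_")[1]) <= max_visit_report]
    summaries = [_summarize(nm, draws[nm], rhat.get(nm, np.nan))
                 for nm in report]
    return FitResult(
        summaries=summaries, draws=draws,
        alpha_names=[f"alpha_{t}" for t in range(data.n_visits)],
        converged=converged, rhat=rhat, max_visit_report=max_visit_report,
    )


def _rhat(draws: dict[str, np.ndarray], fixed: dict[str, float]) -> dict[str, float]:
    rhat = {}
    for nm, arr in draws.items():
        if nm in fixed or np.ptp(arr) == 0:
            rhat[nm] = np.nan
            continue
        rhat[nm] = float(az.rhat(az.convert_to_dataset(arr))["x"].values)
    return rhat


def _summarize(name: str, arr: np.ndarray, rhat: float) -> PosteriorSummary:
    pooled = arr.reshape(-1)
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    return PosteriorSummary(
        name=name, mean=float(pooled.mean()), ci_low=float(lo),
        ci_high=float(hi), significant=not (lo <= 0.0 <= hi), rhat=rhat,
    )


def trajectory_differences(fit: FitResult, max_t: int | None = None
                           ) -> list[PosteriorSummary]:
    """Posterior summaries of the visit contrasts alpha_t - alpha_0.

    Differences are computed draw-wise and then summarised; a contrast is
    significant when its 95% credible interval excludes zero.  ``max_t``
    defaults to the fit's reporting horizon (visit 5).
    """
    if max_t is None:
        max_t = min(fit.max_visit_report, len(fit.alpha_names) - 1)
    if max_t > len(fit.alpha_names) - 1:
        raise ValueError(
            f"visit {max_t} beyond fitted visits (max "
            f"{len(fit.alpha_names) - 1})")
    base = fit.draws["alpha_0"]
    out = []
    for t in range(1, max_t + 1):
        diff = fit.draws[f"alpha_{t}"] - base
        out.append(_summarize(f"alpha_{t}-alpha_0", diff, np.nan))
    return out


def covariate_effects(fit: FitResult) -> list[PosteriorSummary]:
    """Summaries of the loss-of-ambulation, ACE/ARB and baseline-age effects."""
    return [fit[nm] for nm in LOC_EXTRA]


# ---------------------------------------------------------------------------
# likelihood

def log_likelihood(panel: CohortPanel, params: ModelParams,
                   response_name: str | None = None) -> float:
    """Observed-data log-likelihood of the DMD group under ``params``.

    Responses contribute the sequential Gaussian terms of the AR(1)
    recursion; observed covariate indicators contribute their Bernoulli
    log-mass under eta.  Subjects must have complete consecutive responses
    (no internal gaps) — latent-variable handling lives in :func:`fit_model`.
    """
    df = panel.subset(group="dmd", response_name=response_name)
    if df.empty:
        raise ValueError("no DMD records to evaluate")
    if df["response_name"].nunique() > 1:
        raise ValueError("panel holds several responses; pass response_name")

    total = 0.0
    const = -0.5 * np.log(2.0 * np.pi * params.sigma_y**2)
    for _, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit")
        vis = sub["visit"].to_numpy()
        yv = sub["value"].to_numpy(dtype=float)
        obs = ~np.isnan(yv)
        if not obs.any():
            continue
        L = vis[obs].max() + 1
        if not np.array_equal(vis[: L], np.arange(L)) or np.isnan(yv[:L]).any():
            raise ValueError(
                f"subject {sub['subject_id'].iloc[0]!r} has gaps in its "
                "visit sequence; log_likelihood requires complete responses")
        if L > params.n_visits:
            raise ValueError(
                f"subject has visit {L - 1} but params.alpha covers only "
                f"{params.n_visits} visits")
        loa = np.nan_to_num(sub["loa"].to_numpy(dtype=float)[:L])
        ace = np.nan_to_num(sub["ace"].to_numpy(dtype=float)[:L])
        mu = params.mu(np.arange(L), loa, ace,
                       np.full(L, sub["age_baseline"].iloc[0]))
        e = yv[:L] - mu
        innov = e.copy()
        innov[1:] -= params.beta * e[:-1]
        total += L * const - 0.5 * float(innov @ innov) / params.sigma_y**2

        for col, eta in (("loa", params.eta_loa), ("ace", params.eta_ace)):
            x = sub[col].to_numpy(dtype=float)[:L]
            seen = ~np.isnan(x)
            total += float(xlogy(x[seen], eta).sum()
                           + xlogy(1.0 - x[seen], 1.0 - eta).sum())
    return float(total)
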