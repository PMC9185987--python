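"""Shared domain types: model parameters, simulation config, cohort panel.

The longitudinal model is

    y_{i,t} ~ N(mu_{i,t}, sigma_y^2)                                  t = 0
    y_{i,t} ~ N(mu_{i,t} + beta * (y_{i,t-1} - mu_{i,t-1}), sigma_y^2)  t >= 1

    mu_{i,t} = alpha_t + gamma_loa * loa_{i,t} + gamma_ace * ace_{i,t}
               + delta * age_i0

with loa_{i,t} ~ Bernoulli(eta_loa) and ace_{i,t} ~ Bernoulli(eta_ace)
independently per subject-visit.  ``ModelParams`` holds one point in that
parameter space; it is both the generating truth of the simulator and the
state vector of the Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: long-format cohort CSV column order
PANEL_COLUMNS = [
    "subject_id",
    "group",
    "visit",
    "age_baseline",
    "loa",
    "ace",
    "response_name",
    "value",
]


class ConfigurationError(ValueError):
    """Invalid simulation or model configuration."""


@dataclass
class ModelParams:
    """Parameters of the AR(1) longitudinal model.

    Parameters
    ----------
    alpha
        Visit intercepts ``alpha_t`` for t = 0..T, in response units.
    beta
        Autoregressive coefficient on the previous visit's residual
        (dimensionless).
    gamma_loa, gamma_ace
        Additive effects of loss of ambulation and of ACE-inhibitor/ARB use
        (response units).
    delta
        Effect per year of baseline age (response units / year).
    sigma_y
        Residual (innovation) standard deviation, > 0.
    eta_loa, eta_ace
        Bernoulli probabilities of the two indicators, in [0, 1].
    """

    alpha: np.ndarray
    beta: float = 0.0
    gamma_loa: float = 0.0
    gamma_ace: float = 0.0
    delta: float = 0.0
    sigma_y: float = 1.0
    eta_loa: float = 0.25
    eta_ace: float = 0.59

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.alpha.ndim != 1 or self.alpha.size < 1:
            raise ConfigurationError("alpha must be a 1-D vector of length >= 1")
        if not self.sigma_y > 0:
            raise ConfigurationError(f"sigma_y must be > 0, got {self.sigma_y}")
        for name in ("eta_loa", "eta_ace"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")

    @property
    def n_visits(self) -> int:
        return self.alpha.size

    def mu(self, visit: np.ndarray, loa: np.ndarray, ace: np.ndarray,
           age_baseline: np.ndarray) -> np.ndarray:
        """Regression mean mu_{i,t} for vectors of visit/covariate values."""
        return (
            self.alpha[np.asarray(visit, dtype=int)]
            + self.gamma_loa * np.asarray(loa, dtype=float)
            + self.gamma_ace * np.asarray(ace, dtype=float)
            + self.delta * np.asarray(age_baseline, dtype=float)
        )

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class SimulationConfig:
    """Configuration of a synthetic DMD cohort.

    Defaults reproduce the study conditions of the natural-history cohort the
    package emulates: 47 longitudinal DMD subjects followed annually, baseline
    age 11.2 +/- 3.1 years truncated to [5.3, 18.1].
    """

    params: ModelParams
    n_subjects: int = 47
    n_visits: int = 6
    baseline_age_mean: float = 11.2
    baseline_age_sd: float = 3.1
    age_range: tuple[float, float] = (5.3, 18.1)
    loa_mode: str = "monotone"
    dropout_prob: float = 0.0
    response_name: str = "peak_strain_pct"
    n_controls: int = 0
    control_mean: float | None = None
    control_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")
        if self.n_visits > self.params.n_visits:
            raise ConfigurationError(
                f"params.alpha has {self.params.n_visits} visits but "
                f"n_visits={self.n_visits} requested"
            )
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigurationError(
                f"dropout_prob must lie in [0, 1), got {self.dropout_prob}"
            )
        if self.loa_mode not in ("iid", "monotone"):
            raise ConfigurationError(
                f"loa_mode must be 'iid' or 'monotone', got {self.loa_mode!r}"
            )
        if self.n_controls and (self.control_mean is None or self.control_sd is None):
            raise ConfigurationError(
                "control_mean and control_sd are required when n_controls > 0"
            )


@dataclass
class CohortPanel:
    """Long-format panel of subject-visit records.

    ``records`` has columns ``subject_id, group, visit, age_baseline, loa,
    ace, response_name, value``; covariate indicators and the response may be
    missing (NaN).  Control subjects carry only visit 0.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PANEL_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        self.records = self.records[PANEL_COLUMNS].reset_index(drop=True)
        dup = self.records.duplicated(["subject_id", "visit", "response_name"])
        if dup.any():
            raise ValueError(
                "duplicate (subject_id, visit, response_name) records: "
                f"{self.records.loc[dup, ['subject_id', 'visit', 'response_name']].to_dict('records')[:3]}"
            )
        ctrl = self.records[self.records["group"] == "control"]
        if len(ctrl) and (ctrl["visit"] != 0).any():
            raise ValueError("control subjects may only have visit 0")

    def subset(self, group: str | None = None,
               response_name: str | None = None) -> pd.DataFrame:
        df = self.records
        if group is not None:
            df = df[df["group"] == group]
        if response_name is not None:
            df = df[df["response_name"] == response_name]
        return df.reset_index(drop=True)

    @property
    def subjects(self) -> Sequence:
        return self.records["subject_id"].unique()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CohortPanel":
        df = pd.read_csv(path, dtype={"subject_id": str, "group": str,
                                      "response_name": str})
        df["visit"] = df["visit"].astype(int)
        return cls(df)

    @classmethod
    def from_records(cls, frames: Sequence[pd.DataFrame]) -> "CohortPanel":
        return cls(pd.concat(frames, ignore_index=True))
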