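"""Synthetic longitudinal cohorts and segmental strain-time curves.

The generator runs the AR(1) longitudinal model forward exactly as written,
so the fitter in :mod:`dmdlv.model` can be validated by parameter recovery:
baseline ages from a truncated normal, loss-of-ambulation and ACE/ARB
indicators as Bernoulli draws (optionally made monotone, since loss of
ambulation is clinically absorbing), responses from the sequential Gaussian
recursion, and missing-at-random dropout as geometric censoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dmdlv.types import (
    PANEL_COLUMNS,
    CohortPanel,
    ConfigurationError,
    ModelParams,
    SimulationConfig,
)
from dmdlv.strain import SEGMENTS, StrainTimeCourse

# Posterior-mean peak-strain trajectory of the DMD natural-history cohort,
# baseline through year 5 (circumferential strain, %).
PEAK_STRAIN_ALPHA = (-17.9, -17.0, -16.7, -17.0, -16.0, -14.9)
# Left-ventricular mass trajectory (g), baseline through year 5.
LVM_ALPHA = (73.5, 77.7, 83.7, 85.0, 90.4, 86.6)


def peak_strain_params(beta: float = 0.3, sigma_y: float = 1.5,
                       gamma_loa: float = 0.0, gamma_ace: float = 0.0,
                       delta: float = 0.0) -> ModelParams:
    """Generating parameters for a peak circumferential strain response."""
    return ModelParams(alpha=np.array(PEAK_STRAIN_ALPHA), beta=beta,
                       gamma_loa=gamma_loa, gamma_ace=gamma_ace, delta=delta,
                       sigma_y=sigma_y)


def lvm_params(beta: float = 0.3, sigma_y: float = 10.0,
               gamma_loa: float = 6.5, gamma_ace: float = -5.6,
               delta: float = 4.8) -> ModelParams:
    """Generating parameters for a left-ventricular mass response (g)."""
    return ModelParams(alpha=np.array(LVM_ALPHA), beta=beta,
                       gamma_loa=gamma_loa, gamma_ace=gamma_ace, delta=delta,
                       sigma_y=sigma_y)


def _truncated_normal_ages(rng: np.random.Generator, n: int, mean: float,
                           sd: float, lo: float, hi: float) -> np.ndarray:
    # rejection sampling; acceptance is high for the default window
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _indicator_matrix(rng: np.random.Generator, n: int, t: int, eta: float,
                      monotone: bool) -> np.ndarray:
    ind = (rng.random((n, t)) < eta).astype(float)
    if monotone:
        ind = np.maximum.accumulate(ind, axis=1)
    return ind


def simulate_cohort(config: SimulationConfig) -> CohortPanel:
    """Generate a cohort by running the longitudinal model forward.

    DMD subjects get ``config.n_visits`` annual visits of the response named
    ``config.response_name``; optional control subjects get a single baseline
    visit drawn i.i.d. from N(control_mean, control_sd^2).  With ``loa_mode
    = "iid"`` covariates follow the model's independent Bernoulli draws
    exactly; ``"monotone"`` makes each indicator absorbing once set.

    Reproducible: the same config (including seed) gives identical output.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    n, T = config.n_subjects, config.n_visits

    age = _truncated_normal_ages(rng, n, config.baseline_age_mean,
                                 config.baseline_age_sd, *config.age_range)
    loa = _indicator_matrix(rng, n, T, p.eta_loa, config.loa_mode == "monotone")
    ace = _indicator_matrix(rng, n, T, p.eta_ace, config.loa_mode == "monotone")

    mu = (p.alpha[None, :T] + p.gamma_loa * loa + p.gamma_ace * ace
          + p.delta * age[:, None])
    y = np.empty((n, T))
    eps = rng.normal(0.0, p.sigma_y, size=(n, T))
    y[:, 0] = mu[:, 0] + eps[:, 0]
    for t in range(1, T):
        y[:, t] = mu[:, t] + p.beta * (y[:, t - 1] - mu[:, t - 1]) + eps[:, t]

    sid = np.repeat([f"dmd{i:03d}" for i in range(n)], T)
    frame = pd.DataFrame({
        "subject_id": sid,
        "group": "dmd",
        "visit": np.tile(np.arange(T), n),
        "age_baseline": np.repeat(age, T),
        "loa": loa.ravel(),
        "ace": ace.ravel(),
        "response_name": config.response_name,
        "value": y.ravel(),
    })

    frames = [frame]
    if config.n_controls:
        cage = _truncated_normal_ages(rng, config.n_controls, 12.1, 4.1, 6.0, 18.3)
        frames.append(pd.DataFrame({
            "subject_id": [f"ctl{i:03d}" for i in range(config.n_controls)],
            "group": "control",
            "visit": 0,
            "age_baseline": cage,
            "loa": 0.0,
            "ace": np.nan,
            "response_name": config.response_name,
            "value": rng.normal(config.control_mean, config.control_sd,
                                size=config.n_controls),
        }))
    panel = CohortPanel.from_records(frames)
    if config.dropout_prob > 0:
        panel = apply_dropout(panel, config.dropout_prob,
                              seed=rng.integers(2**31))
    return panel


def apply_dropout(panel: CohortPanel, dropout_prob: float,
                  seed: int) -> CohortPanel:
    """Censor each DMD subject from a geometric visit onward.

    Each subject independently leaves the study after ``D ~ Geometric(p)``
    retained visits (support 1, 2, ...), so visit 0 is never removed.
    Records beyond the dropout visit are kept with missing response and
    covariates — dropout is independent of the response, hence missing at
    random by construction.
    """
    if not 0.0 <= dropout_prob < 1.0:
        raise ConfigurationError(
            f"dropout_prob must lie in [0, 1), got {dropout_prob}")
    if dropout_prob == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    df = panel.records.copy()
    dmd_ids = df.loc[df["group"] == "dmd", "subject_id"].unique()
    retained = {s: rng.geometric(dropout_prob) for s in dmd_ids}
    cut = df["subject_id"].map(lambda s: retained.get(s, np.inf))
    gone = df["visit"] >= cut
    df.loc[gone, ["value", "loa", "ace"]] = np.nan
    return CohortPanel(df)


def simulate_strain_timecourse(segment_peaks, n_frames: int = 20,
                               phase_offsets=None, noise_sd: float = 0.0,
                               seed: int = 0) -> StrainTimeCourse:
    """Synthetic 6-segment circumferential strain curves over one cycle.

    Each segment follows a raised-cosine contraction template
    ``peak * 0.5 * (1 - cos(2*pi*(f - offset)/n_frames))`` — zero strain at
    end diastole (frame 0), most-negative at mid cycle, back to zero —
    circularly shifted by its phase offset (frames) and perturbed by
    Gaussian noise.  With zero noise and integer offsets the per-segment
    extremum equals the specified peak exactly for even ``n_frames``.

    Peaks must be <= 0: circumferential strain is negative at contraction.
    """
    peaks = np.asarray(segment_peaks, dtype=float)
    if peaks.shape != (6,):
        raise ValueError(f"segment_peaks must have shape (6,), got {peaks.shape}")
    if np.any(peaks > 0):
        raise ValueError("segment peaks must be <= 0 (contraction is negative)")
    if n_frames < 8:
        raise ValueError(f"n_frames must be >= 8, got {n_frames}")
    offsets = np.zeros(6) if phase_offsets is None else np.asarray(phase_offsets, float)
    if offsets.shape != (6,):
        raise ValueError("phase_offsets must have shape (6,)")

    rng = np.random.default_rng(seed)
    f = np.arange(n_frames)[None, :]
    phase = 2.0 * np.pi * (f - offsets[:, None]) / n_frames
    values = peaks[:, None] * 0.5 * (1.0 - np.cos(phase))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return StrainTimeCourse(segments=list(SEGMENTS), values=values)


def write_strain_csv(tc: StrainTimeCourse, path) -> None:
    """6-row CSV with a segment-label first column."""
    pd.DataFrame(tc.values, index=list(tc.segments)).to_csv(
        path, header=False)


def read_strain_csv(path) -> StrainTimeCourse:
    df = pd.read_csv(path, header=None, index_col=0)
    return StrainTimeCourse(segments=list(df.index), values=df.to_numpy(float))
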