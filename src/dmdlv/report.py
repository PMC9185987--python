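"""MCID classification, trajectory change summaries and table assembly.

The minimal clinically important difference (MCID) is distribution-based:
a cardiac parameter's one-year change is clinically relevant when its
magnitude reaches a fraction (1/3 by default, 1/2 as the stricter
convention) of the parameter's baseline standard deviation.  The one-year
change is model-based — the posterior mean of alpha_1 - alpha_0 — not a raw
year-over-year delta.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

MCID_COLUMNS = ["parameter", "baseline_sd", "threshold_fraction", "threshold",
                "one_year_change", "abs_change", "meets_mcid", "missing_sd"]


def mcid_classify(changes: Mapping[str, float],
                  baseline_sds: Mapping[str, float],
                  fraction: float = 1 / 3) -> pd.DataFrame:
    """Classify per-parameter one-year changes against the MCID threshold.

    ``changes`` maps parameter name to the signed one-year change;
    ``baseline_sds`` maps name to the baseline SD.  The threshold is
    ``fraction * baseline_sd`` and a change meets the MCID when
    ``|change| >= threshold`` (boundary counts).  Parameters without a
    baseline SD get a row with ``missing_sd=True`` and are excluded from the
    count.  The number of parameters meeting the MCID is in
    ``df.attrs["n_meeting"]``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    rows = []
    for name, change in changes.items():
        sd = baseline_sds.get(name)
        if sd is None or (isinstance(sd, float) and np.isnan(sd)):
            rows.append({"parameter": name, "baseline_sd": np.nan,
                         "threshold_fraction": fraction, "threshold": np.nan,
                         "one_year_change": change, "abs_change": abs(change),
                         "meets_mcid": False, "missing_sd": True})
            continue
        thr = fraction * float(sd)
        rows.append({"parameter": name, "baseline_sd": float(sd),
                     "threshold_fraction": fraction, "threshold": thr,
                     "one_year_change": change, "abs_change": abs(change),
                     "meets_mcid": abs(change) >= thr, "missing_sd": False})
    df = pd.DataFrame(rows, columns=MCID_COLUMNS)
    df.attrs["n_meeting"] = int(df.loc[~df["missing_sd"], "meets_mcid"].sum())
    return df


def absolute_change(trajectory: Mapping[int, float], from_t: int,
                    to_t: int) -> tuple[float, float]:
    """Signed and absolute change between two visit estimates."""
    for t in (from_t, to_t):
        if t not in trajectory:
            raise KeyError(f"visit {t} missing from trajectory")
    signed = trajectory[to_t] - trajectory[from_t]
    return signed, abs(signed)


def percent_change(trajectory: Mapping[int, float], from_t: int,
                   to_t: int) -> float:
    """Absolute change as a percentage of the baseline magnitude."""
    signed, mag = absolute_change(trajectory, from_t, to_t)
    base = trajectory[from_t]
    if base == 0:
        raise ZeroDivisionError("percent change undefined at zero baseline")
    return 100.0 * mag / abs(base)


_REQUIRED = {
    "posteriors": ["parameter", "mean", "ci_low", "ci_high", "significant"],
    "comparisons": ["response", "t", "df", "p"],
    "mcid": MCID_COLUMNS,
}


def assemble_tables(posteriors: pd.DataFrame | None = None,
                    comparisons: pd.DataFrame | None = None,
                    mcid: pd.DataFrame | None = None,
                    out_dir: str | Path | None = None,
                    metadata: Mapping[str, object] | None = None,
                    ) -> dict[str, pd.DataFrame]:
    """Validate and (optionally) write the run's report tables.

    Each provided table is schema-checked; violations raise a ``ValueError``
    naming the offending columns.  With ``out_dir`` set, tables go to
    ``<name>.csv`` plus a ``run_metadata.json``-style Markdown block with
    seeds and sampler settings.  Assembly is a pure function of its inputs.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, df in (("posteriors", posteriors), ("comparisons", comparisons),
                     ("mcid", mcid)):
        if df is None:
            continue
        missing = [c for c in _REQUIRED[name] if c not in df.columns]
        if missing:
            raise ValueError(
                f"table {name!r} is missing required columns: {missing}")
        tables[name] = df.copy()

    if "posteriors" in tables:
        t = tables["posteriors"]
        t["estimate_95ci"] = [
            f"{m:.1f}{'*' if s else ''} ({lo:.1f}, {hi:.1f})"
            for m, lo, hi, s in zip(t["mean"], t["ci_low"], t["ci_high"],
                                    t["significant"])
        ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(tables.items()):
            df.to_csv(out / f"{name}.csv", index=False)
        lines = ["# Run metadata", ""]
        for k, v in sorted((metadata or {}).items()):
            lines.append(f"- {k}: {v}")
        (out / "run_metadata.md").write_text("\n".join(lines) + "\n")
    return tables


#: the 17 cardiac parameters tracked for MCID purposes: composite and global
#: strain, the six segmental strains, dyssynchrony, AV-plane displacement,
#: and the volumetric/mass measures with their BSA-indexed forms
CARDIAC_PARAMETERS = (
    "peak_strain_pct", "global_strain_pct",
    "anterior_strain_pct", "anteroseptal_strain_pct",
    "inferoseptal_strain_pct", "inferior_strain_pct",
    "inferolateral_strain_pct", "anterolateral_strain_pct",
    "cure", "lvapd_mm",
    "lvef_pct", "lvm_g", "lvmi_g_m2",
    "lvesv_ml", "lvesvi_ml_m2", "lvedv_ml", "lvedvi_ml_m2",
)
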