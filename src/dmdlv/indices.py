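"""Volumetric, mass and atrioventricular-plane indices from chamber measures.

Units follow the study tables: LVM in g, volumes in mL, LVAPD in mm
(negative toward the apex), indexed values in g/m^2 or mL/m^2.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)


def body_surface_area(height_cm: float, weight_kg: float,
                      formula: str = "mosteller") -> float:
    """Body surface area in m^2.

    Mosteller (default, standard in pediatric cardiology):
    ``sqrt(height * weight / 3600)``.  ``formula="dubois"`` gives the
    Du Bois & Du Bois variant ``0.007184 * height^0.725 * weight^0.425``.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(
            f"height and weight must be positive, got {height_cm}, {weight_kg}")
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


def ejection_fraction(lvedv_ml: float, lvesv_ml: float) -> float:
    """Left-ventricular ejection fraction, % = 100 * (EDV - ESV) / EDV."""
    if lvedv_ml <= 0:
        raise ValueError(f"LVEDV must be positive, got {lvedv_ml}")
    if not 0 <= lvesv_ml <= lvedv_ml:
        raise ValueError(
            f"LVESV must lie in [0, LVEDV], got ESV={lvesv_ml}, EDV={lvedv_ml}")
    return 100.0 * (lvedv_ml - lvesv_ml) / lvedv_ml


def normalize_index(value: float, bsa_m2: float) -> float:
    """BSA-indexed mass or volume (g/m^2, mL/m^2)."""
    if bsa_m2 <= 0:
        raise ValueError(f"BSA must be positive, got {bsa_m2}")
    return value / bsa_m2


def lvapd(landmark_displacements: Mapping[str, Sequence[float]]) -> float:
    """Atrioventricular-plane displacement, mm.

    ``landmark_displacements`` maps view name (``"two_chamber"``,
    ``"four_chamber"``) to the diastole-to-systole displacements of the
    septal, lateral and apical landmarks in that view.  Landmarks are
    averaged within each view, then the view means are averaged; sign is
    preserved (negative = toward the apex).  A single available view is used
    alone with a warning.
    """
    view_means = [sum(v) / len(v) for v in landmark_displacements.values() if len(v)]
    if not view_means:
        raise ValueError("need at least one view with >= 1 landmark displacement")
    if len(view_means) == 1:
        logger.warning("LVAPD computed from a single view")
    return sum(view_means) / len(view_means)
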