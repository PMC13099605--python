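"""Native-MS stoichiometry assignment via a theoretical mass ladder.

An L8S8 holoenzyme built from two SSu species of different mass produces a
ladder of nine possible neutral masses: substituting one light subunit for
one heavy one shifts the deconvoluted mass by a fixed step. Assigning each
deconvoluted native-MS peak to its nearest ladder rung reads out the SSu
stoichiometry of that population.

Two ladder constructions are supported:

* **empirical** — anchored on the measured masses of the two homogeneous
  holoenzymes (rung 0 = all-light, rung 8 = all-heavy). Preferred for real
  spectra, because measured native masses carry adducts and processing
  differences that sequence masses miss.
* **theoretical** — from the two subunit masses plus an invariant core mass
  (L8 plus anything shared).

Convention: ``k`` counts copies of species A, the *heavy* (GB1-tagged)
subunit, i.e. the number of substitutions above the all-light anchor. The
ratio label is printed light:heavy, ``(8-k):k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import N_SITES

__all__ = ["MassLadder", "build_ladder", "assign_peaks", "verify_subunit_presence"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MassLadder:
    """Nine theoretical holoenzyme masses for k = 0..8 heavy subunits."""

    rungs: np.ndarray
    mode: str  # "empirical" | "theoretical"
    step_kDa: float = field(init=False)

    def __post_init__(self):
        rungs = np.asarray(self.rungs, dtype=float)
        if rungs.shape != (N_SITES + 1,):
            raise ValueError(f"ladder must have {N_SITES + 1} rungs")
        steps = np.diff(rungs)
        if np.any(steps <= 0):
            raise ValueError("ladder rungs must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("ladder rungs must be evenly spaced")
        object.__setattr__(self, "rungs", rungs)
        object.__setattr__(self, "step_kDa", float(steps[0]))


def build_ladder(
    anchor_low_kDa: float | None = None,
    anchor_high_kDa: float | None = None,
    *,
    mass_light_kDa: float | None = None,
    mass_heavy_kDa: float | None = None,
    core_mass_kDa: float | None = None,
) -> MassLadder:
    """Build the stoichiometry mass ladder.

    Either pass the two empirical anchors (masses of the homogeneous
    all-light and all-heavy holoenzymes), or the two subunit masses plus the
    invariant core mass for a theoretical ladder.
    """
    empirical = anchor_low_kDa is not None or anchor_high_kDa is not None
    theoretical = any(v is not None for v in (mass_light_kDa, mass_heavy_kDa, core_mass_kDa))
    if empirical and theoretical:
        raise ValueError("give either empirical anchors or theoretical masses, not both")
    k = np.arange(N_SITES + 1)
    if empirical:
        if anchor_low_kDa is None or anchor_high_kDa is None:
            raise ValueError("both anchors are required in empirical mode")
        if not (0 < anchor_low_kDa < anchor_high_kDa):
            raise ValueError("anchors must satisfy 0 < anchor_low < anchor_high")
        step = (anchor_high_kDa - anchor_low_kDa) / N_SITES
        return MassLadder(rungs=anchor_low_kDa + k * step, mode="empirical")
    if None in (mass_light_kDa, mass_heavy_kDa, core_mass_kDa):
        raise ValueError("theoretical mode needs both subunit masses and the core mass")
    if min(mass_light_kDa, mass_heavy_kDa, core_mass_kDa) <= 0:
        raise ValueError("masses must be positive")
    if mass_heavy_kDa <= mass_light_kDa:
        raise ValueError(
            "subunit masses must differ (heavy > light); equal masses give a degenerate ladder"
        )
    rungs = core_mass_kDa + (N_SITES - k) * mass_light_kDa + k * mass_heavy_kDa
    return MassLadder(rungs=rungs, mode="theoretical")


def assign_peaks(
    peaks: pd.DataFrame, ladder: MassLadder, tolerance_kDa: float | None = None
) -> pd.DataFrame:
    """Assign each deconvoluted native-MS peak to its nearest ladder rung.

    ``peaks`` needs a ``mass_kDa`` column (``rel_intensity`` is carried
    through if present). Ties between two rungs are broken toward the lower
    k with a warning. Default tolerance is step/4. Returns one row per peak:
    ``mass_kDa, k_heavy, ratio_light_heavy, theoretical_mass_kDa,
    residual_kDa, within_tolerance``; the frame's ``attrs['n_distinct_k']``
    summarizes how many distinct stoichiometries were seen.
    """
    if tolerance_kDa is None:
        tolerance_kDa = ladder.step_kDa / 4.0
    if tolerance_kDa <= 0:
        raise ValueError("tolerance must be positive")
    cols = [
        "mass_kDa", "rel_intensity", "k_heavy", "ratio_light_heavy",
        "theoretical_mass_kDa", "residual_kDa", "within_tolerance",
    ]
    if len(peaks) == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["n_distinct_k"] = 0
        return out
    masses = peaks["mass_kDa"].to_numpy(dtype=float)
    if np.any(masses <= 0):
        raise ValueError("peak masses must be positive")
    rel = peaks["rel_intensity"].to_numpy() if "rel_intensity" in peaks else np.full(len(masses), np.nan)
    dist = np.abs(masses[:, None] - ladder.rungs[None, :])
    k_assigned = np.argmin(dist, axis=1)  # argmin takes the first minimum: ties go to lower k
    tie = np.isclose(dist[np.arange(len(masses)), k_assigned],
                     np.abs(masses - ladder.rungs[np.minimum(k_assigned + 1, N_SITES)]))
    for i in np.nonzero(tie & (k_assigned < N_SITES))[0]:
        logger.warning(
            "peak %.4f kDa is equidistant between rungs k=%d and k=%d; assigned lower k",
            masses[i], k_assigned[i], k_assigned[i] + 1,
        )
    residual = masses - ladder.rungs[k_assigned]
    out = pd.DataFrame(
        {
            "mass_kDa": masses,
            "rel_intensity": rel,
            "k_heavy": k_assigned,
            "ratio_light_heavy": [f"{N_SITES - k}:{k}" for k in k_assigned],
            "theoretical_mass_kDa": ladder.rungs[k_assigned],
            "residual_kDa": residual,
            "within_tolerance": np.abs(residual) <= tolerance_kDa,
        }
    )
    out.attrs["n_distinct_k"] = int(len(np.unique(k_assigned)))
    return out


def verify_subunit_presence(
    denatured: pd.DataFrame, expected_masses_kDa: dict[str, float], tolerance_kDa: float = 0.05
) -> pd.DataFrame:
    """Check denatured-MS peaks for each expected subunit mass.

    Returns one row per expected species: ``species, expected_mass_kDa,
    present, matched_mass_kDa, residual_kDa`` (NaN when absent).
    """
    masses = denatured["mass_kDa"].to_numpy(dtype=float) if len(denatured) else np.array([])
    rows = []
    for species, mass in expected_masses_kDa.items():
        if mass <= 0:
            raise ValueError(f"expected mass for {species} must be positive")
        if len(masses):
            i = int(np.argmin(np.abs(masses - mass)))
            residual = masses[i] - mass
            present = abs(residual) <= tolerance_kDa
        else:
            residual, present, i = np.nan, False, -1
        rows.append(
            {
                "species": species,
                "expected_mass_kDa": mass,
                "present": bool(present),
                "matched_mass_kDa": masses[i] if present else np.nan,
                "residual_kDa": residual if present else np.nan,
            }
        )
    return pd.DataFrame(rows)
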