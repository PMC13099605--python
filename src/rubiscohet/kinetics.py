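"""Kinetic and stability model fits.

Four analyses used to characterize purified Rubisco variants:

* Michaelis–Menten carboxylation kinetics, v = V_Cmax·[S]/(K_m + [S]),
  fit per replicate by bounded nonlinear least squares; the "average model"
  is the mean of per-replicate parameters.
* Two-point Arrhenius activation energy from V_Cmax at two temperatures:
  E_a = R·ln(v2/v1) / (1/T1 - 1/T2), temperatures in kelvin.
* Activity recovery of RuBP-inhibited enzyme (slow-binding inhibitor
  release), default instantaneous-rate form v(t) = v_final·(1 - e^(-k_obs·t));
  the integrated product form P(t) = v_s·t - (v_s/k_obs)·(1 - e^(-k_obs·t))
  is selectable.
* Thermal melt curves: Boltzmann sigmoid for T_m and transition slope, with
  a two-state van't Hoff analysis giving ΔH_vH at T_m and ΔG°_unfolding
  extrapolated to a reference temperature (default 25 °C, ΔCp = 0 unless
  configured). By construction ΔG°_unfolding(T_m) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MMFit",
    "RecoveryFit",
    "MeltFit",
    "fit_michaelis_menten",
    "activation_energy",
    "activation_energy_per_replicate",
    "fit_recovery",
    "fit_melt",
    "GAS_CONSTANT_KJ",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1


def _kelvin(t_C: float) -> float:
    return t_C + 273.15


@dataclass(frozen=True)
class MMFit:
    replicate: str
    v_cmax: float
    km_mM: float
    se_v_cmax: float
    se_km: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class RecoveryFit:
    replicate: str
    k_obs: float  # min^-1
    v_final: float
    se_k_obs: float
    converged: bool
    model: str


@dataclass(frozen=True)
class MeltFit:
    tm_C: float
    slope_C: float
    baseline_low: float
    baseline_high: float
    dH_vH_kJ: float
    dG_unfold_kJ: float  # at ref_temperature_C
    ref_temperature_C: float
    converged: bool


def _mm_model(S, V, K):
    return V * S / (K + S)


def _mm_init(S, v):
    """Linearized (Hanes–Woolf) start values: S/v = S/V + K/V."""
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(S[pos], S[pos] / v[pos], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    return max(v.max(), 1e-6) * 1.2, np.median(S)


def fit_michaelis_menten(measurements: pd.DataFrame) -> tuple[list[MMFit], dict]:
    """Fit v = V·S/(K+S) to each replicate; return fits and the average model.

    ``measurements`` columns: replicate, substrate_mM, rate. Replicates need
    at least three distinct substrate levels. Non-converged or degenerate
    replicates (e.g. all-zero rates) are flagged and excluded from the
    average, with a log entry.
    """
    fits: list[MMFit] = []
    for rep, grp in measurements.groupby("replicate", sort=False):
        S = grp["substrate_mM"].to_numpy(dtype=float)
        v = grp["rate"].to_numpy(dtype=float)
        if len(np.unique(S)) < 3:
            raise ValueError(f"replicate {rep}: need >=3 distinct substrate levels")
        if np.all(v <= 0):
            logger.warning("replicate %s: no positive rates, fit flagged", rep)
            fits.append(MMFit(str(rep), np.nan, np.nan, np.nan, np.nan, False, len(S)))
            continue
        V0, K0 = _mm_init(S, v)
        try:
            popt, pcov = curve_fit(
                _mm_model, S, v, p0=[V0, K0], bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10_000,
            )
            se = np.sqrt(np.diag(pcov))
            fits.append(MMFit(str(rep), float(popt[0]), float(popt[1]),
                              float(se[0]), float(se[1]), True, len(S)))
        except RuntimeError:
            logger.warning("replicate %s: Michaelis–Menten fit did not converge", rep)
            fits.append(MMFit(str(rep), np.nan, np.nan, np.nan, np.nan, False, len(S)))
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no replicate produced a converged Michaelis–Menten fit")
    average = {
        "v_cmax": float(np.mean([f.v_cmax for f in good])),
        "km_mM": float(np.mean([f.km_mM for f in good])),
        "sd_v_cmax": float(np.std([f.v_cmax for f in good], ddof=1)) if len(good) > 1 else np.nan,
        "sd_km": float(np.std([f.km_mM for f in good], ddof=1)) if len(good) > 1 else np.nan,
        "n_replicates": len(good),
    }
    return fits, average


def activation_energy(v1: float, v2: float, t1_C: float, t2_C: float) -> float:
    """Two-point Arrhenius activation energy in kJ/mol.

    ``v1`` at ``t1_C`` and ``v2`` at ``t2_C``; symmetric under swapping the
    two (rate, temperature) pairs.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("rates must be positive")
    if t1_C == t2_C:
        raise ValueError("temperatures must differ")
    T1, T2 = _kelvin(t1_C), _kelvin(t2_C)
    return float(GAS_CONSTANT_KJ * np.log(v2 / v1) / (1.0 / T1 - 1.0 / T2))


def activation_energy_per_replicate(
    fits_t1: list[MMFit], fits_t2: list[MMFit], t1_C: float, t2_C: float
) -> pd.DataFrame:
    """Replicate-paired E_a from V_Cmax fits at two temperatures.

    Pairs replicates by id; unpaired or non-converged replicates are dropped
    with a log entry.
    """
    d1 = {f.replicate: f for f in fits_t1 if f.converged}
    d2 = {f.replicate: f for f in fits_t2 if f.converged}
    rows = []
    for rep in d1:
        if rep not in d2:
            logger.warning("replicate %s present at %g °C only, dropped from E_a", rep, t1_C)
            continue
        rows.append(
            {"replicate": rep,
             "ea_kJ_mol": activation_energy(d1[rep].v_cmax, d2[rep].v_cmax, t1_C, t2_C)}
        )
    return pd.DataFrame(rows)


def _recovery_rate(t, v_final, k_obs):
    return v_final * (1.0 - np.exp(-k_obs * t))


def _recovery_product(t, v_s, k_obs):
    return v_s * t - (v_s / k_obs) * (1.0 - np.exp(-k_obs * t))


def fit_recovery(time_courses: pd.DataFrame, model: str = "rate") -> list[RecoveryFit]:
    """Fit inhibitor-release kinetics to each replicate's recovery trace.

    ``time_courses`` columns: replicate, time_min, activity. ``model`` is
    "rate" (v(t), default) or "product" (integrated P(t)). Traces with no
    resolvable exponential (e.g. constant activity) are flagged rather than
    reported with a spurious k_obs.
    """
    if model not in ("rate", "product"):
        raise ValueError(f"unknown recovery model {model!r}")
    func = _recovery_rate if model == "rate" else _recovery_product
    fits: list[RecoveryFit] = []
    for rep, grp in time_courses.groupby("replicate", sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        y = grp["activity"].to_numpy(dtype=float)
        if len(t) < 4:
            raise ValueError(f"replicate {rep}: need >=4 time points")
        span = y.max() - y.min()
        if span <= 1e-12 * max(abs(y.max()), 1.0):
            logger.warning("replicate %s: constant trace, k_obs unidentifiable", rep)
            fits.append(RecoveryFit(str(rep), np.nan, np.nan, np.nan, False, model))
            continue
        k0 = 1.0 / max(np.median(t), 1e-9)
        p0 = [max(y.max(), 1e-9), k0] if model == "rate" else [max(span / max(t.max(), 1e-9), 1e-9), k0]
        try:
            popt, pcov = curve_fit(
                func, t, y, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000
            )
            se = np.sqrt(np.diag(pcov))
            fits.append(RecoveryFit(str(rep), float(popt[1]), float(popt[0]),
                                    float(se[1]), True, model))
        except RuntimeError:
            logger.warning("replicate %s: recovery fit did not converge", rep)
            fits.append(RecoveryFit(str(rep), np.nan, np.nan, np.nan, False, model))
    return fits


def _boltzmann(T, low, high, tm, slope):
    return low + (high - low) / (1.0 + np.exp((tm - T) / slope))


def fit_melt(
    curve: pd.DataFrame,
    *,
    ref_temperature_C: float = 25.0,
    dCp_kJ: float = 0.0,
) -> MeltFit:
    """Boltzmann sigmoid fit of a melt curve plus two-state van't Hoff analysis.

    ``curve`` columns: temperature_C, signal. The van't Hoff enthalpy comes
    from the transition steepness, ΔH_vH = R·T_m²/m with the slope m in
    kelvin; ΔG°_unfolding is extrapolated to ``ref_temperature_C`` with the
    Gibbs–Helmholtz relation (ΔCp defaults to 0):

        ΔG(T) = ΔH_vH·(1 - T/T_m) - ΔCp·[(T_m - T) + T·ln(T/T_m)]
    """
    T = curve["temperature_C"].to_numpy(dtype=float)
    y = curve["signal"].to_numpy(dtype=float)
    if len(T) < 5:
        raise ValueError("need >=5 temperature points")
    span = y.max() - y.min()
    if span <= 1e-12 * max(abs(y.max()), 1.0):
        raise ValueError("no melt transition detected (flat signal)")
    tm0 = float(T[np.argmin(np.abs(y - (y.min() + span / 2.0)))])
    p0 = [y.min(), y.max(), tm0, max((T.max() - T.min()) / 20.0, 0.5)]
    try:
        popt, _ = curve_fit(
            _boltzmann, T, y, p0=p0,
            bounds=([-np.inf, -np.inf, T.min(), 1e-6], [np.inf, np.inf, T.max(), np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise ValueError("no melt transition detected (fit failed)") from exc
    low, high, tm, slope = (float(x) for x in popt)
    tm_K = _kelvin(tm)
    dH = GAS_CONSTANT_KJ * tm_K**2 / slope  # slope in °C == kelvin width
    T_ref = _kelvin(ref_temperature_C)
    dG = dH * (1.0 - T_ref / tm_K) - dCp_kJ * ((tm_K - T_ref) + T_ref * np.log(T_ref / tm_K))
    return MeltFit(
        tm_C=tm, slope_C=slope, baseline_low=low, baseline_high=high,
        dH_vH_kJ=float(dH), dG_unfold_kJ=float(dG),
        ref_temperature_C=ref_temperature_C, converged=True,
    )
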