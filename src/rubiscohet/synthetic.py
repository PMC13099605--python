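"""Synthetic data generators for every stage of the heterogeneity pipeline.

These generators emulate the statistical structure of the wet-lab inputs:

* a pool of L8S8 holoenzymes whose His-tagged copy number k follows either
  the binomial model or the sequential-preference chain
  (:func:`simulate_assembly`);
* tandem His-then-Strep affinity capture with configurable per-column
  efficiencies — constant, or dependent on the number of matching tags —
  tracked by western-blot band intensities with multiplicative lognormal
  densitometry noise (:func:`simulate_purification`);
* deconvoluted native-MS mass ladders with Gaussian mass error and a
  detection floor (:func:`simulate_ms_peaks`);
* Michaelis–Menten rate tables, first-order activity-recovery time courses
  and Boltzmann melt curves (:func:`simulate_michaelis_menten` and friends).

All functions are seed-reproducible: the same seed gives bit-identical
output. Column survival is computed with expected-count weights by default
(each holoenzyme contributes its retention probability), which makes the
noise-free pipeline exactly deterministic; Bernoulli sampling of survival is
available with ``sampling=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import N_SITES, _preference_step_probs

__all__ = [
    "SubunitSpecies",
    "AssemblyScenario",
    "ColumnEfficiencyModel",
    "NoiseModel",
    "simulate_assembly",
    "retention_probability",
    "simulate_purification",
    "simulate_experiment",
    "simulate_ms_peaks",
    "simulate_michaelis_menten",
    "simulate_recovery",
    "simulate_melt",
    "simulate_kinetic_data",
    "boltzmann",
]

STAGES = ("soluble", "post_his", "post_strep")
ANTIBODIES = ("anti_his", "anti_strep")


@dataclass(frozen=True)
class SubunitSpecies:
    """One tagged SSu variant, e.g. the 15.62 kDa Strep-tagged or the
    22.48 kDa GB1-His-tagged small subunit."""

    species_id: str
    tag: str  # "His" | "Strep" | "GB1-His"
    mass_kDa: float

    def __post_init__(self):
        if self.mass_kDa <= 0:
            raise ValueError("mass_kDa must be positive")
        if self.tag not in ("His", "Strep", "GB1-His"):
            raise ValueError(f"unknown tag {self.tag!r}")


@dataclass(frozen=True)
class AssemblyScenario:
    """Parameters of one simulated holoenzyme pool."""

    skew_p: float
    preference_alpha: float = 1.0
    n_holoenzymes: int = 100_000
    n_sites: int = N_SITES
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.skew_p <= 1.0):
            raise ValueError("skew_p must lie in [0, 1]")
        if self.preference_alpha <= 0:
            raise ValueError("preference_alpha must be positive")
        if self.n_holoenzymes < 1:
            raise ValueError("n_holoenzymes must be >= 1")


@dataclass(frozen=True)
class ColumnEfficiencyModel:
    """Capture behaviour of the His and Strep affinity columns.

    Under ``constant`` dependence a holoenzyme with at least one matching tag
    is retained with probability ``e_his`` / ``e_strep``; with no matching
    tag it is always lost. Under ``per_tag``, each matching tag is captured
    independently with probability ``q``, so a holoenzyme with m matching
    tags is retained with probability 1 - (1 - q)^m — the failure mode in
    which the corrected estimator is known to underestimate heterogeneity.
    """

    e_his: float = 1.0
    e_strep: float = 1.0
    tag_dependence: str = "constant"  # "constant" | "per_tag"
    q_his: float = 0.5
    q_strep: float = 0.5

    def __post_init__(self):
        for name in ("e_his", "e_strep"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.tag_dependence not in ("constant", "per_tag"):
            raise ValueError(f"unknown tag_dependence {self.tag_dependence!r}")
        for name in ("q_his", "q_strep"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings shared across generators."""

    densitometry_cv: float = 0.0
    signal_mode: str = "per_holoenzyme"  # or "per_tag"
    ms_mass_sd_kDa: float = 0.0
    ms_detection_floor: float = 0.0

    def __post_init__(self):
        if self.densitometry_cv < 0 or self.ms_mass_sd_kDa < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if not (0.0 <= self.ms_detection_floor < 1.0):
            raise ValueError("ms_detection_floor must lie in [0, 1)")
        if self.signal_mode not in ("per_holoenzyme", "per_tag"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")


def simulate_assembly(scenario: AssemblyScenario) -> pd.DataFrame:
    """Draw a pool of holoenzymes; column ``k`` counts His-tagged subunits.

    With ``preference_alpha == 1`` each of the 8 sites is an independent
    Bernoulli(skew_p), so k ~ Binomial(8, skew_p). Otherwise sites are
    filled sequentially and the odds of repeating the species at the
    previous site are multiplied by alpha.
    """
    rng = np.random.default_rng(scenario.seed)
    n, p, alpha = scenario.n_holoenzymes, scenario.skew_p, scenario.preference_alpha
    if alpha == 1.0 or p in (0.0, 1.0):
        k = rng.binomial(scenario.n_sites, p, size=n)
    else:
        p_hh, p_sh = _preference_step_probs(p, alpha)
        prev = rng.random(n) < p
        k = prev.astype(np.int64)
        for _ in range(scenario.n_sites - 1):
            p_his = np.where(prev, p_hh, p_sh)
            prev = rng.random(n) < p_his
            k += prev
    return pd.DataFrame({"k": k})


def retention_probability(m_tags: np.ndarray, e: float, q: float, tag_dependence: str) -> np.ndarray:
    """Probability a holoenzyme with ``m_tags`` matching tags survives a column."""
    m = np.asarray(m_tags)
    if tag_dependence == "constant":
        return np.where(m > 0, e, 0.0)
    return 1.0 - (1.0 - q) ** m


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_purification(
    holoenzymes: pd.DataFrame,
    columns: ColumnEfficiencyModel,
    noise: NoiseModel,
    seed: int = 0,
    *,
    replicate_id: str = "rep1",
    gain_his: float = 1.0,
    gain_strep: float = 1.0,
    sampling: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Push a holoenzyme pool through His-then-Strep capture and blot it.

    Returns a tidy record table with one row per (stage, antibody):
    ``replicate, stage, antibody, intensity`` — the western-blot band
    intensities an experimenter would quantify — plus a ground-truth sidecar
    dict (true heterogeneous fraction, stage-wise expected counts).

    Band intensity is the surviving holoenzyme count (``per_holoenzyme``
    signal) or the surviving matching-tag count (``per_tag`` signal), times
    the antibody gain, times unit-mean lognormal densitometry noise.
    """
    if gain_his <= 0 or gain_strep <= 0:
        raise ValueError("antibody gains must be positive")
    rng = np.random.default_rng(seed)
    k = holoenzymes["k"].to_numpy()
    m_his = k
    m_strep = N_SITES - k

    r_his = retention_probability(m_his, columns.e_his, columns.q_his, columns.tag_dependence)
    r_strep = retention_probability(m_strep, columns.e_strep, columns.q_strep, columns.tag_dependence)
    if sampling:
        w_soluble = np.ones_like(r_his)
        w_post_his = (rng.random(len(k)) < r_his).astype(float)
        w_post_strep = w_post_his * (rng.random(len(k)) < r_strep)
    else:
        w_soluble = np.ones_like(r_his)
        w_post_his = r_his
        w_post_strep = r_his * r_strep

    def band(weights, antibody):
        # an antibody only sees holoenzymes that carry its tag
        m = m_his if antibody == "anti_his" else m_strep
        if noise.signal_mode == "per_tag":
            return float(np.sum(weights * m))
        return float(np.sum(weights[m > 0]))

    rows = []
    stage_weights = dict(zip(STAGES, (w_soluble, w_post_his, w_post_strep)))
    for stage in STAGES:
        for antibody, gain in zip(ANTIBODIES, (gain_his, gain_strep)):
            signal = band(stage_weights[stage], antibody) * gain
            signal *= float(_lognormal_factor(rng, noise.densitometry_cv))
            rows.append(
                {"replicate": replicate_id, "stage": stage, "antibody": antibody, "intensity": signal}
            )
    truth = {
        "true_heterogeneous_fraction": float(np.mean((k >= 1) & (k <= N_SITES - 1))),
        "true_skew": float(np.mean(k) / N_SITES),
        "count_soluble": float(w_soluble.sum()),
        "count_post_his": float(w_post_his.sum()),
        "count_post_strep": float(w_post_strep.sum()),
    }
    return pd.DataFrame(rows), truth


def simulate_experiment(
    scenario: AssemblyScenario,
    columns: ColumnEfficiencyModel,
    noise: NoiseModel,
    n_replicates: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full multi-replicate purification experiment.

    Each replicate draws its own holoenzyme pool (independent seeds derived
    from ``seed``) and is blotted at all three stages with both antibodies.
    Returns (records, truth) tidy frames.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    records, truths = [], []
    for i, ss in enumerate(seeds):
        child = np.random.default_rng(ss)
        pool_seed, blot_seed = child.integers(0, 2**31 - 1, size=2)
        pool = simulate_assembly(
            AssemblyScenario(
                skew_p=scenario.skew_p,
                preference_alpha=scenario.preference_alpha,
                n_holoenzymes=scenario.n_holoenzymes,
                seed=int(pool_seed),
            )
        )
        rec, truth = simulate_purification(
            pool, columns, noise, seed=int(blot_seed), replicate_id=f"rep{i + 1}"
        )
        records.append(rec)
        truth["replicate"] = f"rep{i + 1}"
        truths.append(truth)
    return pd.concat(records, ignore_index=True), pd.DataFrame(truths)


def simulate_ms_peaks(
    counts: np.ndarray,
    species_a: SubunitSpecies,
    species_b: SubunitSpecies,
    core_mass_kDa: float,
    noise: NoiseModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Deconvoluted native-MS peak list for a stoichiometry distribution.

    ``counts[k]`` is the abundance of holoenzymes carrying k copies of
    species A (and 8-k of species B). Each represented k yields one neutral
    mass peak at ``core + k*mass_A + (8-k)*mass_B`` plus Gaussian mass
    error; peaks whose relative abundance (fraction of total) falls below
    the detection floor are suppressed.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_SITES + 1,) or np.any(counts < 0):
        raise ValueError(f"counts must be {N_SITES + 1} nonnegative abundances")
    if core_mass_kDa <= 0:
        raise ValueError("core_mass_kDa must be positive")
    rng = np.random.default_rng(seed)
    rel = counts / counts.sum()
    ks = np.nonzero(rel >= max(noise.ms_detection_floor, np.finfo(float).tiny))[0]
    masses = (
        core_mass_kDa
        + ks * species_a.mass_kDa
        + (N_SITES - ks) * species_b.mass_kDa
        + rng.normal(0.0, noise.ms_mass_sd_kDa, size=len(ks))
    )
    return pd.DataFrame({"mass_kDa": masses, "rel_intensity": rel[ks], "true_k": ks})


# ---------------------------------------------------------------------------
# kinetics fixtures


def boltzmann(T, baseline_low, baseline_high, tm, slope):
    """Boltzmann sigmoid used for thermal melt curves."""
    T = np.asarray(T, dtype=float)
    return baseline_low + (baseline_high - baseline_low) / (1.0 + np.exp((tm - T) / slope))


def simulate_michaelis_menten(
    v_cmax: float,
    km_mM: float,
    substrate_mM,
    *,
    n_replicates: int = 5,
    cv: float = 0.0,
    temperature_C: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rate table v = V*S/(K+S) with multiplicative Gaussian noise (sd = cv*v)."""
    if v_cmax <= 0 or km_mM <= 0:
        raise ValueError("v_cmax and km_mM must be positive")
    rng = np.random.default_rng(seed)
    S = np.asarray(substrate_mM, dtype=float)
    rows = []
    for i in range(n_replicates):
        v = v_cmax * S / (km_mM + S)
        v_obs = v * (1.0 + rng.normal(0.0, cv, size=len(S))) if cv > 0 else v
        rows.append(
            pd.DataFrame(
                {
                    "replicate": f"rep{i + 1}",
                    "substrate_mM": S,
                    "rate": v_obs,
                    "temperature_C": temperature_C,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_recovery(
    k_obs: float,
    v_final: float,
    time_min,
    *,
    n_replicates: int = 5,
    sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Activity-recovery time courses v(t) = v_final*(1 - exp(-k_obs*t))."""
    if k_obs <= 0 or v_final <= 0:
        raise ValueError("k_obs and v_final must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(time_min, dtype=float)
    rows = []
    for i in range(n_replicates):
        v = v_final * (1.0 - np.exp(-k_obs * t))
        v_obs = v + rng.normal(0.0, sd, size=len(t)) if sd > 0 else v
        rows.append(pd.DataFrame({"replicate": f"rep{i + 1}", "time_min": t, "activity": v_obs}))
    return pd.concat(rows, ignore_index=True)


def simulate_melt(
    tm_C: float,
    slope_C: float = 2.0,
    temperature_C=None,
    *,
    baseline_low: float = 0.0,
    baseline_high: float = 1.0,
    sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Boltzmann melt curve (temperature_C, signal) with additive noise."""
    if tm_C <= 0 or slope_C <= 0:
        raise ValueError("tm_C and slope_C must be positive")
    if temperature_C is None:
        temperature_C = np.arange(25.0, 95.0 + 0.5, 0.5)
    rng = np.random.default_rng(seed)
    T = np.asarray(temperature_C, dtype=float)
    sig = boltzmann(T, baseline_low, baseline_high, tm_C, slope_C)
    if sd > 0:
        sig = sig + rng.normal(0.0, sd, size=len(T))
    return pd.DataFrame({"temperature_C": T, "signal": sig})


def simulate_kinetic_data(params: dict, design: dict | None = None, seed: int = 0) -> dict:
    """Bundle of kinetics fixtures: MM rates at two temperatures, recovery
    time courses and a melt curve, from one parameter dict.

    ``params`` keys (defaults in parentheses): v_cmax_25 (20), v_cmax_35
    (40), km_mM (0.5), k_obs (0.3), v_final (1.0), tm_C (60), cv (0), sd (0).
    """
    design = design or {}
    p = {
        "v_cmax_25": 20.0,
        "v_cmax_35": 40.0,
        "km_mM": 0.5,
        "k_obs": 0.3,
        "v_final": 1.0,
        "tm_C": 60.0,
        "cv": 0.0,
        "sd": 0.0,
        **params,
    }
    substrate = design.get("substrate_mM", [0.05, 0.1, 0.2, 0.4, 0.8, 1.6])
    times = design.get("time_min", np.linspace(0.5, 10.0, 10))
    n_rep = design.get("n_replicates", 5)
    s1, s2, s3, s4 = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
    rates = pd.concat(
        [
            simulate_michaelis_menten(
                p["v_cmax_25"], p["km_mM"], substrate,
                n_replicates=n_rep, cv=p["cv"], temperature_C=25.0, seed=int(s1),
            ),
            simulate_michaelis_menten(
                p["v_cmax_35"], p["km_mM"], substrate,
                n_replicates=n_rep, cv=p["cv"], temperature_C=35.0, seed=int(s2),
            ),
        ],
        ignore_index=True,
    )
    recovery = simulate_recovery(
        p["k_obs"], p["v_final"], times, n_replicates=n_rep, sd=p["sd"], seed=int(s3)
    )
    melt = simulate_melt(p["tm_C"], sd=p["sd"], seed=int(s4))
    return {"rates": rates, "recovery": recovery, "melt": melt}
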