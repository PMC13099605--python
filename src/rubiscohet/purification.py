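"""Column-efficiency-corrected heterogeneity and His-skew estimators.

The experiment tracks the amount of L8S8 Rubisco at each stage of a tandem
affinity purification (total soluble → HisTrap → StrepTrap) by western
blotting with anti-His and anti-Strep antibodies. Because neither column is
perfectly efficient, the raw post-Strep amount understates the true
dual-tagged (SSu-heterogeneous) amount. The correction:

* His-column efficiency  e_his  = anti_his(post_his) / anti_his(soluble)
  (every holoenzyme blotted by anti-His carries a His tag, so its loss across
  the His column is pure column inefficiency);
* Strep-column efficiency e_strep = anti_strep(post_strep) / anti_strep(post_his)
  (everything anti-Strep-positive entering the Strep column carries a Strep tag);
* corrected dual-tagged amount  a_hetero = anti_strep(post_strep) / (e_his * e_strep);
* corrected initial totals by inclusion–exclusion:
  a_total = a_his_initial + a_strep_initial - a_hetero, valid when every
  holoenzyme carries at least one of the two tags (true for dual-SSu
  constructs).

Measured heterogeneity is a_hetero / a_total per replicate; the His-skew is
a_his_initial / a_total. Estimates are made per replicate, then summarized
(mean ± SD), matching the n = 6 replicate protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assembly import SkewEstimate, predicted_heterogeneity

__all__ = [
    "estimate_efficiencies",
    "correct_amounts",
    "his_skew",
    "measured_heterogeneity",
    "HeterogeneitySummary",
    "compare_measured_vs_predicted",
]

logger = logging.getLogger(__name__)

_REQUIRED = {
    ("soluble", "anti_his"),
    ("soluble", "anti_strep"),
    ("post_his", "anti_his"),
    ("post_his", "anti_strep"),
    ("post_strep", "anti_strep"),
}


def _pivot(records: pd.DataFrame) -> pd.DataFrame:
    """Wide view: one row per replicate, one column per (stage, antibody)."""
    required_cols = {"replicate", "stage", "antibody", "intensity"}
    missing = required_cols - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    # optional flow-through rows are accepted and ignored
    records = records[records["stage"].isin(("soluble", "post_his", "post_strep"))]
    dup = records.duplicated(subset=["replicate", "stage", "antibody"])
    if dup.any():
        raise ValueError("duplicate (replicate, stage, antibody) rows in records")
    if (records["intensity"] < 0).any():
        raise ValueError("intensities must be nonnegative")
    return records.pivot(index="replicate", columns=["stage", "antibody"], values="intensity")


def estimate_efficiencies(
    records: pd.DataFrame, *, cap_at_one: bool = True
) -> pd.DataFrame:
    """Per-replicate column efficiencies from stage-tracked band intensities.

    Returns a frame indexed by replicate with columns ``e_his``, ``e_strep``,
    ``excluded`` (bool) and ``reason``. Replicates with a zero or missing
    denominator are excluded with a logged reason rather than propagating
    NaN. Ratios above 1 (densitometry noise) are capped at 1 with a warning
    unless ``cap_at_one`` is False.
    """
    wide = _pivot(records)
    rows = []
    for rep, row in wide.iterrows():
        reason = ""
        e_his = e_strep = np.nan
        try:
            vals = {key: row.get(key, np.nan) for key in _REQUIRED}
        except KeyError:
            vals = {}
        missing = [k for k, v in vals.items() if pd.isna(v)]
        if missing:
            reason = f"missing intensities: {sorted(missing)}"
        elif vals[("soluble", "anti_his")] == 0:
            reason = "zero anti_his soluble intensity (His-efficiency denominator)"
        elif vals[("post_his", "anti_strep")] == 0:
            reason = "zero anti_strep post_his intensity (Strep-efficiency denominator)"
        else:
            e_his = vals[("post_his", "anti_his")] / vals[("soluble", "anti_his")]
            e_strep = vals[("post_strep", "anti_strep")] / vals[("post_his", "anti_strep")]
            for name, val in (("e_his", e_his), ("e_strep", e_strep)):
                if val > 1.0 and cap_at_one:
                    logger.warning(
                        "replicate %s: %s = %.4g > 1, capped at 1 (densitometry noise)",
                        rep, name, val,
                    )
            if cap_at_one:
                e_his, e_strep = min(e_his, 1.0), min(e_strep, 1.0)
        if reason:
            logger.warning("replicate %s excluded: %s", rep, reason)
        rows.append(
            {"replicate": rep, "e_his": e_his, "e_strep": e_strep,
             "excluded": bool(reason), "reason": reason}
        )
    return pd.DataFrame(rows).set_index("replicate")


def correct_amounts(
    records: pd.DataFrame,
    efficiencies: pd.DataFrame | None = None,
    *,
    antibody_calibration: float = 1.0,
) -> pd.DataFrame:
    """Efficiency-corrected initial amounts per replicate.

    ``antibody_calibration`` is the gain ratio anti_his/anti_strep used to
    map anti-Strep intensities onto the anti-His scale (1 when both signals
    are normalized to a shared standard). Output columns: ``a_his_initial``,
    ``a_strep_initial``, ``a_hetero``, ``a_total_initial``, ``e_his``,
    ``e_strep``, ``flagged`` (True when the corrected dual amount exceeds a
    single-tag amount, an internal inconsistency that is reported, not
    silently repaired).
    """
    if antibody_calibration <= 0:
        raise ValueError("antibody_calibration must be positive")
    if efficiencies is None:
        efficiencies = estimate_efficiencies(records)
    wide = _pivot(records)
    rows = []
    for rep, row in wide.iterrows():
        if rep not in efficiencies.index or efficiencies.loc[rep, "excluded"]:
            continue
        e_his = float(efficiencies.loc[rep, "e_his"])
        e_strep = float(efficiencies.loc[rep, "e_strep"])
        if not (0.0 < e_his <= 1.0 and 0.0 < e_strep <= 1.0):
            logger.warning("replicate %s: efficiencies outside (0, 1], skipped", rep)
            continue
        a_his = float(row[("soluble", "anti_his")])
        a_strep = float(row[("soluble", "anti_strep")]) / antibody_calibration
        a_het = float(row[("post_strep", "anti_strep")]) / antibody_calibration / (e_his * e_strep)
        flagged = a_het > min(a_his, a_strep) * (1.0 + 1e-9)
        if flagged:
            logger.warning(
                "replicate %s: corrected dual amount %.4g exceeds min single-tag "
                "amount %.4g; retained but flagged", rep, a_het, min(a_his, a_strep),
            )
        rows.append(
            {
                "replicate": rep,
                "a_his_initial": a_his,
                "a_strep_initial": a_strep,
                "a_hetero": a_het,
                "a_total_initial": a_his + a_strep - a_het,
                "e_his": e_his,
                "e_strep": e_strep,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("replicate")


def his_skew(corrected: pd.DataFrame, *, total: str = "sum") -> SkewEstimate:
    """His-skew: His-tagged fraction of the initial Rubisco signal.

    ``total="sum"`` (default) divides by a_his_initial + a_strep_initial,
    which is the total SSu signal when band intensity scales with tag count
    — the scale on which the His-skew is defined (it recovers the assembly
    probability p exactly from noise-free tag-proportional blots).
    ``total="inclusion_exclusion"`` divides by the deduplicated holoenzyme
    total a_his + a_strep - a_hetero, appropriate when band intensity counts
    complexes; there the ratio is the His-containing complex fraction.
    """
    if total == "sum":
        denom = corrected["a_his_initial"] + corrected["a_strep_initial"]
    elif total == "inclusion_exclusion":
        denom = corrected["a_total_initial"]
    else:
        raise ValueError(f"unknown total mode {total!r}")
    if (denom <= 0).any():
        raise ValueError("total initial amount must be positive for every replicate")
    per_rep = (corrected["a_his_initial"] / denom).clip(0.0, 1.0)
    return SkewEstimate(p_hat=float(per_rep.mean()), per_replicate=tuple(per_rep))


@dataclass(frozen=True)
class HeterogeneitySummary:
    per_replicate: pd.Series
    mean: float
    sd: float


def measured_heterogeneity(corrected: pd.DataFrame) -> HeterogeneitySummary:
    """Corrected heterogeneous fraction a_hetero / a_total per replicate."""
    if (corrected["a_total_initial"] <= 0).any():
        raise ValueError("a_total_initial must be positive for every replicate")
    frac = corrected["a_hetero"] / corrected["a_total_initial"]
    frac.name = "measured_heterogeneity"
    return HeterogeneitySummary(
        per_replicate=frac, mean=float(frac.mean()),
        sd=float(frac.std(ddof=1)) if len(frac) > 1 else float("nan"),
    )


def compare_measured_vs_predicted(
    skew: SkewEstimate, measured: HeterogeneitySummary, *, alpha: float = 0.05
) -> dict:
    """Paired comparison of binomial-predicted vs measured heterogeneity.

    Prediction uses each replicate's own skew. Reports the mean difference
    (predicted - measured), a paired two-sided t-test, and the direction
    flag ``predicted_exceeds_measured``.
    """
    if skew.n_replicates != len(measured.per_replicate):
        raise ValueError("replicate sets of skew and measured heterogeneity differ")
    predicted = np.array([predicted_heterogeneity(p) for p in skew.per_replicate])
    meas = measured.per_replicate.to_numpy()
    diff = predicted - meas
    if len(diff) >= 2 and np.std(diff, ddof=1) > 0:
        t_stat, p_value = sps.ttest_rel(predicted, meas)
    else:
        t_stat, p_value = np.nan, np.nan
    return {
        "predicted_mean": float(predicted.mean()),
        "measured_mean": float(meas.mean()),
        "mean_difference": float(diff.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
        "significant": bool(p_value < alpha) if np.isfinite(p_value) else False,
        "predicted_exceeds_measured": bool(diff.mean() > 0),
        "per_replicate_predicted": predicted.tolist(),
        "per_replicate_measured": meas.tolist(),
    }
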