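"""Design-based estimation for complex-survey data (weights, strata, PSUs).

Implements survey-weighted means and proportions with Taylor-linearization
variance, the standard estimator for stratified multistage samples.  For a
ratio mean ``theta = sum(w x) / sum(w)`` the linearized score per unit is
``z_i = w_i (x_i - theta) / sum(w)``; the variance estimate sums
between-PSU variation of PSU score totals within each stratum:

    Var = sum_h  n_h / (n_h - 1)  sum_j (Z_hj - Zbar_h)^2

with ``Z_hj`` the score total of PSU j in stratum h and ``n_h`` the number
of PSUs in stratum h.  Confidence intervals use a t reference with the
design degrees of freedom (#PSUs - #strata).  Unadjusted (SRS-style)
standard errors are reported alongside for comparability with analyses
that ignore the design.  Estimates are invariant to rescaling all weights
by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "WeightedSummary",
    "weighted_mean",
    "weighted_proportion",
    "summarize_groups",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Per-unit design fields: sampling weight, stratum id, PSU id."""

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        s = np.asarray(self.stratum)
        p = np.asarray(self.psu)
        if not (len(w) == len(s) == len(p)):
            raise ValueError("weight, stratum, psu must have equal length")
        if len(w) == 0:
            raise ValueError("empty design")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("all survey weights must be finite and > 0")
        object.__setattr__(self, "weight", w)
        object.__setattr__(self, "stratum", s.astype(str))
        object.__setattr__(self, "psu", p.astype(str))

    def __len__(self) -> int:
        return len(self.weight)

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.weight[mask], self.stratum[mask], self.psu[mask])


@dataclass(frozen=True)
class WeightedSummary:
    """A design-based estimate with its SE, t-interval and design df."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    n_unweighted: int
    se_srs: float = float("nan")

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket {self.estimate}"
            )


def _taylor_variance(x: np.ndarray, design: SurveyDesign, theta: float, *, single_psu: str = "error") -> tuple[float, int]:
    """Taylor-linearization variance of the ratio mean and the design df."""
    wsum = design.weight.sum()
    z = design.weight * (x - theta) / wsum
    strata = pd.unique(design.stratum)
    var = 0.0
    n_psu_total = 0
    for h in strata:
        in_h = design.stratum == h
        psu_ids = pd.unique(design.psu[in_h])
        n_h = len(psu_ids)
        n_psu_total += n_h
        if n_h < 2:
            if single_psu == "certainty":
                continue  # certainty unit: contributes no between-PSU variance
            raise ValueError(
                f"stratum {h!r} has a single PSU; variance is not estimable "
                "(pass single_psu='certainty' to treat it as a certainty unit)"
            )
        totals = np.array([z[in_h & (design.psu == p)].sum() for p in psu_ids])
        var += n_h / (n_h - 1) * np.sum((totals - totals.mean()) ** 2)
    df = n_psu_total - len(strata)
    return float(var), max(df, 1)


def weighted_mean(
    values: Sequence[float] | np.ndarray,
    design: SurveyDesign,
    *,
    single_psu: str = "error",
    alpha: float = 0.05,
) -> WeightedSummary:
    """Survey-weighted mean with Taylor-linearization SE and t-interval.

    ``single_psu`` controls lonely-PSU strata: ``"error"`` (default) raises
    naming the stratum; ``"certainty"`` treats the stratum as a certainty
    unit contributing no between-PSU variance.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != len(design):
        raise ValueError("values and design must have equal length")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    theta = float(np.sum(design.weight * x) / np.sum(design.weight))
    if len(x) == 1:
        return WeightedSummary(theta, 0.0, theta, theta, 1, 1, se_srs=0.0)
    var, df = _taylor_variance(x, design, theta, single_psu=single_psu)
    se = float(np.sqrt(var))
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    # SRS-style SE of the weighted mean, ignoring strata/PSUs.
    wnorm = design.weight / design.weight.sum()
    se_srs = float(np.sqrt(np.sum(wnorm**2 * (x - theta) ** 2) * len(x) / max(len(x) - 1, 1)))
    return WeightedSummary(
        estimate=theta,
        se=se,
        ci_low=theta - tcrit * se,
        ci_high=theta + tcrit * se,
        df=df,
        n_unweighted=len(x),
        se_srs=se_srs,
    )


def weighted_proportion(
    indicator: Sequence[bool] | np.ndarray,
    design: SurveyDesign,
    *,
    single_psu: str = "error",
    alpha: float = 0.05,
) -> WeightedSummary:
    """Survey-weighted proportion: the weighted mean of a 0/1 indicator."""
    x = np.asarray(indicator, dtype=float)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("indicator must be 0/1 or boolean")
    return weighted_mean(x, design, single_psu=single_psu, alpha=alpha)


_NUTRIENT_COLS = {
    "energy": "baseline_energy",
    "sodium": "baseline_sodium",
    "added_sugar": "baseline_sugar",
    "fiber": "baseline_fiber",
}

_CATEGORICALS = ("sex", "race_ethnicity", "education", "pir_category", "food_security_level")


def summarize_groups(
    participants: pd.DataFrame,
    intake_table: pd.DataFrame,
    delta_table: pd.DataFrame | None = None,
    impact_tables: dict[tuple[str, str], "object"] | None = None,
    *,
    single_psu: str = "error",
) -> dict[str, pd.DataFrame]:
    """Survey-weighted per-group report tables.

    Parameters
    ----------
    participants : frame with participant_id, snap, weight, stratum, psu and
        demographic/derived-category columns.
    intake_table : frame with participant_id, energy/sodium/added_sugar/fiber
        totals (baseline_* naming) and upf_share.
    delta_table : optional long scenario table from
        :func:`upfsim.substitution.run_scenarios`.
    impact_tables : optional mapping (group, scenario) ->
        :class:`upfsim.health.HealthImpactResult`.

    Returns a dict of frames: ``baseline`` (Table-1-style weighted means and
    95% CIs of dietary variables per group), ``demographics`` (weighted
    category percentages), ``deltas`` (per-scenario weighted mean deltas)
    and ``impacts`` when supplied.  Groups with no members raise.
    """
    merged = participants.merge(intake_table, on="participant_id", how="inner")
    if merged.empty:
        raise ValueError("no participants after merging intake table")
    out: dict[str, pd.DataFrame] = {}

    groups = {"snap": merged["snap"].astype(bool), "nonsnap": ~merged["snap"].astype(bool)}
    for name, mask in groups.items():
        if not mask.any():
            raise ValueError(f"group {name!r} is empty")

    def _design(frame: pd.DataFrame) -> SurveyDesign:
        return SurveyDesign(
            frame["weight"].to_numpy(), frame["stratum"].to_numpy(), frame["psu"].to_numpy()
        )

    rows = []
    for name, mask in groups.items():
        sub = merged[mask]
        design = _design(sub)
        for var, col in {**_NUTRIENT_COLS, "upf_share": "upf_share"}.items():
            if col not in sub.columns:
                continue
            ws = weighted_mean(sub[col].to_numpy(), design, single_psu=single_psu)
            rows.append(
                {
                    "group": name,
                    "variable": var,
                    "estimate": ws.estimate,
                    "se": ws.se,
                    "ci_low": ws.ci_low,
                    "ci_high": ws.ci_high,
                    "df": ws.df,
                    "n_unweighted": ws.n_unweighted,
                    "se_srs": ws.se_srs,
                }
            )
    out["baseline"] = pd.DataFrame(rows)

    demo_rows = []
    for name, mask in groups.items():
        sub = merged[mask]
        design = _design(sub)
        for var in _CATEGORICALS:
            if var not in sub.columns:
                continue
            for level in sorted(sub[var].astype(str).unique()):
                ws = weighted_proportion(
                    (sub[var].astype(str) == level).to_numpy(),
                    design,
                    single_psu=single_psu,
                )
                demo_rows.append(
                    {
                        "group": name,
                        "variable": var,
                        "level": level,
                        "percent": 100.0 * ws.estimate,
                        "ci_low": 100.0 * ws.ci_low,
                        "ci_high": 100.0 * ws.ci_high,
                    }
                )
    out["demographics"] = pd.DataFrame(demo_rows)

    if delta_table is not None:
        drows = []
        dmerged = delta_table.merge(
            participants[["participant_id", "snap", "weight", "stratum", "psu"]],
            on="participant_id",
        )
        for name in groups:
            sub = dmerged[dmerged["snap"].astype(bool) == (name == "snap")]
            for scenario, chunk in sub.groupby("scenario", sort=True):
                design = _design(chunk)
                row = {"group": name, "scenario": scenario}
                for col in ("d_sodium", "d_sugar", "d_fiber", "d_energy"):
                    ws = weighted_mean(chunk[col].to_numpy(), design, single_psu=single_psu)
                    row[col] = ws.estimate
                    row[f"{col}_ci_low"] = ws.ci_low
                    row[f"{col}_ci_high"] = ws.ci_high
                drows.append(row)
        out["deltas"] = pd.DataFrame(drows)

    if impact_tables is not None:
        irows = []
        for (name, scenario), result in sorted(impact_tables.items()):
            irows.append({"group": name, "scenario": scenario, **result.as_dict()})
        out["impacts"] = pd.DataFrame(irows)

    return out
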