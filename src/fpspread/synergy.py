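"""Median-effect dose-response fitting and Chou-Talalay combination index.

The median-effect model relates dose D to the affected fraction fa through
fa / fu = (D / Dm)^m with fu = 1 - fa, where Dm is the median-effect dose
and m the sigmoidicity. Fitting is ordinary least squares on the classic
linearization log(fa/fu) = m log(D) - m log(Dm). For a constant-ratio
combination producing effect fa at doses (d1, d2), the combination index is

    CI = d1 / Dx1 + d2 / Dx2,   Dx_i = Dm_i * (fa / (1 - fa))^(1 / m_i),

computed under the mutually-exclusive assumption (the method's default);
CI < 1 indicates synergy, CI = 1 Loewe additivity, CI > 1 antagonism. An
optional third term d1*d2/(Dx1*Dx2) covers mutually non-exclusive drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FA_EPS = 1e-3


@dataclass
class DoseResponseModel:
    dm: float  # median-effect dose, units of the input doses
    m: float  # slope of the median-effect plot
    r_squared: float  # fit diagnostic on the linearized scale
    n_points: int

    def __post_init__(self) -> None:
        if self.dm <= 0 or self.m <= 0:
            raise ValueError(f"median-effect parameters must be positive (dm={self.dm}, m={self.m})")

    def fa(self, dose: float) -> float:
        """Predicted affected fraction at a dose."""
        if dose <= 0:
            return 0.0
        ratio = (dose / self.dm) ** self.m
        return ratio / (1 + ratio)

    def dose_for_fa(self, fa: float) -> float:
        """Dose producing affected fraction fa (the Dx of the CI formula).

        Computed in floating point with overflow saturating to inf (a
        degenerate fit with m near 0 can push the exponent out of range);
        callers then see CI contributions of 0 rather than an exception.
        """
        if not 0 < fa < 1:
            raise ValueError("fa must be in (0, 1)")
        with np.errstate(over="ignore"):
            return float(self.dm * np.float64(fa / (1 - fa)) ** (1 / self.m))


@dataclass
class SynergyResult:
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    ci: float

    @property
    def classification(self) -> str:
        if self.ci < 1:
            return "synergy"
        if self.ci > 1:
            return "antagonism"
        return "additive"


def fit_median_effect(
    doses: Sequence[float], affected_fractions: Sequence[float], eps: float = FA_EPS
) -> DoseResponseModel:
    """OLS fit of the median-effect linearization.

    Points at dose 0 are dropped; fa values at the 0/1 boundary are clipped
    to [eps, 1 - eps] with a warning. Needs >= 2 usable dose points.
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(affected_fractions, dtype=float)
    if len(d) != len(fa):
        raise ValueError("doses and affected_fractions must have equal length")
    if (d < 0).any():
        raise ValueError("doses must be non-negative")
    usable = d > 0
    d, fa = d[usable], fa[usable]
    if ((fa <= 0) | (fa >= 1)).any():
        warnings.warn(f"clipping boundary fa values into [{eps}, {1 - eps}]", stacklevel=2)
        fa = np.clip(fa, eps, 1 - eps)
    if len(d) < 2:
        raise ValueError("need >= 2 positive-dose points with fa in (0, 1)")
    x = np.log10(d)
    y = np.log10(fa / (1 - fa))
    fit = stats.linregress(x, y)
    m = float(fit.slope)
    if m <= 0:
        raise ValueError(f"median-effect slope must be positive, got {m:.4g}")
    dm = float(10 ** (-fit.intercept / m))
    r2 = float(fit.rvalue**2) if len(d) > 2 else 1.0
    return DoseResponseModel(dm=dm, m=m, r_squared=r2, n_points=len(d))


def combination_index(
    model1: DoseResponseModel,
    model2: DoseResponseModel,
    d1: float,
    d2: float,
    combo_fa: float,
    mutually_nonexclusive: bool = False,
) -> SynergyResult:
    """Combination index for combo doses (d1, d2) producing effect combo_fa."""
    if not 0 < combo_fa < 1:
        raise ValueError("combo_fa must be in (0, 1)")
    dx1 = model1.dose_for_fa(combo_fa)
    dx2 = model2.dose_for_fa(combo_fa)
    ci = d1 / dx1 + d2 / dx2
    if mutually_nonexclusive:
        ci += (d1 * d2) / (dx1 * dx2)
    return SynergyResult(fa=combo_fa, d1=d1, d2=d2, dx1=dx1, dx2=dx2, ci=ci)


def combo_experiment_report(
    viability: pd.DataFrame,
    eps: float = FA_EPS,
    mutually_nonexclusive: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full CI analysis of a constant-ratio combination viability table.

    ``viability`` needs columns dose_a, dose_b, viability (fraction of the
    vehicle control). Rows with one zero dose are the single-agent series;
    rows with both doses positive are the combination series; rows with both
    zero are vehicle controls used to renormalize. The affected fraction is
    fa = 1 - viability / vehicle. Returns a per-combination-dose CI table
    and a summary with fitted (Dm, m) per drug, the mean CI and its
    classification.
    """
    required = {"dose_a", "dose_b", "viability"}
    if not required.issubset(viability.columns):
        raise ValueError(f"viability table needs columns {sorted(required)}")
    df = viability.copy()
    if (df["viability"] > 1).any():
        warnings.warn("viability values > 1 clipped to 1 (measurement noise)", stacklevel=2)
        df["viability"] = df["viability"].clip(upper=1.0)
    vehicle = df[(df["dose_a"] == 0) & (df["dose_b"] == 0)]
    scale = float(vehicle["viability"].mean()) if len(vehicle) else 1.0
    df["fa"] = 1 - df["viability"] / scale

    only_a = df[(df["dose_a"] > 0) & (df["dose_b"] == 0)]
    only_b = df[(df["dose_b"] > 0) & (df["dose_a"] == 0)]
    combo = df[(df["dose_a"] > 0) & (df["dose_b"] > 0)]
    if len(only_a) < 2 or len(only_b) < 2:
        raise ValueError("need single-agent series (>= 2 doses) for both drugs")
    model_a = fit_median_effect(only_a["dose_a"], only_a["fa"], eps=eps)
    model_b = fit_median_effect(only_b["dose_b"], only_b["fa"], eps=eps)

    rows = []
    for _, rec in combo.iterrows():
        fa = float(np.clip(rec["fa"], eps, 1 - eps))
        res = combination_index(
            model_a,
            model_b,
            float(rec["dose_a"]),
            float(rec["dose_b"]),
            fa,
            mutually_nonexclusive=mutually_nonexclusive,
        )
        rows.append(
            {
                "dose_a": res.d1,
                "dose_b": res.d2,
                "fa": res.fa,
                "dx_a": res.dx1,
                "dx_b": res.dx2,
                "ci": res.ci,
            }
        )
    table = pd.DataFrame(rows, columns=["dose_a", "dose_b", "fa", "dx_a", "dx_b", "ci"])
    mean_ci = float(table["ci"].mean()) if len(table) else float("nan")

    # CI at the half-effect level: treat the constant-ratio combination as a
    # pseudo-drug on its total dose, find the total dose giving fa = 0.5 and
    # split it at the (fixed) mixing ratio.
    ci_ed50 = float("nan")
    if len(combo) >= 2:
        total = (combo["dose_a"] + combo["dose_b"]).to_numpy(dtype=float)
        try:
            combo_model = fit_median_effect(total, combo["fa"], eps=eps)
            frac_a = float(np.median(combo["dose_a"] / total))
            d_tot = combo_model.dose_for_fa(0.5)
            res = combination_index(
                model_a,
                model_b,
                d_tot * frac_a,
                d_tot * (1 - frac_a),
                0.5,
                mutually_nonexclusive=mutually_nonexclusive,
            )
            ci_ed50 = res.ci
        except ValueError:
            pass
    summary = {
        "dm_a": model_a.dm,
        "m_a": model_a.m,
        "r2_a": model_a.r_squared,
        "dm_b": model_b.dm,
        "m_b": model_b.m,
        "r2_b": model_b.r_squared,
        "mean_ci": mean_ci,
        "ci_at_ed50": ci_ed50,
        "classification": "synergy" if mean_ci < 1 else ("antagonism" if mean_ci > 1 else "additive"),
    }
    return table, summary
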