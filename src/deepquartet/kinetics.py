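"""ATPase inhibition-assay analysis.

Plates are tidy :class:`pandas.DataFrame` tables with columns

    compound, inhibitor_conc, k_conc, replicate, activity, is_background

(concentrations in molar, activity in umol Pi/mg/h or raw absorbance).
Background wells are those measured with a saturating blocker (0.5 mM
SCH28080) and, for the K+-competition design, the K+-free wells at each
inhibitor concentration.

Analyses: background subtraction to specific activity, 4-parameter
logistic IC50 fits, global competitive Michaelis-Menten Ki regression
(Vmax and Km shared across inhibitor levels), double-reciprocal
diagnostics, and Henderson-Hasselbalch protonation ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PLATE_COLUMNS = ["compound", "inhibitor_conc", "k_conc", "replicate",
                 "activity", "is_background"]


class PlateDataError(ValueError):
    """Plate table is malformed or missing a background group."""


def specific_activity(plate: pd.DataFrame,
                      group_cols: Sequence[str] = ("compound",)) -> pd.DataFrame:
    """Subtract the mean background of each group from its data wells.

    ``group_cols`` defines the background-matching key: ``("compound",)``
    for the dose-response design (one saturating-blocker background per
    compound) and ``("compound", "inhibitor_conc")`` for the
    K+-competition design (K+-free background at each inhibitor
    concentration).  Returns the corrected non-background rows.
    """
    missing = [c for c in ("activity", "is_background") if c not in plate.columns]
    if missing:
        raise PlateDataError(f"plate lacks columns {missing}")
    bg = plate[plate["is_background"]]
    data = plate[~plate["is_background"]].copy()
    if bg.empty:
        raise PlateDataError("plate has no background wells")
    bg_mean = bg.groupby(list(group_cols))["activity"].mean()
    keys = list(map(tuple, data[list(group_cols)].itertuples(index=False)))
    corrections = []
    for key in keys:
        k = key if len(key) > 1 else key[0]
        if k not in bg_mean.index:
            raise PlateDataError(f"no background wells for group {k!r}")
        corrections.append(bg_mean.loc[k])
    data["activity"] = data["activity"].to_numpy() - np.asarray(corrections)
    return data


# ---------------------------------------------------------------------------
# Dose-response (IC50)
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    se_ic50: float
    se_hill: float
    rss: float
    converged: bool

    def as_dict(self) -> dict:
        return {"ic50": self.ic50, "hill": self.hill, "top": self.top,
                "bottom": self.bottom, "se_ic50": self.se_ic50,
                "se_hill": self.se_hill, "rss": self.rss,
                "converged": self.converged}


def _logistic(c: np.ndarray, ic50: float, hill: float, top: float,
              bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_dose_response(conc: Sequence[float], activity: Sequence[float]
                      ) -> DoseResponseFit:
    """4-parameter logistic fit ``bottom + (top-bottom)/(1+(c/IC50)^h)``.

    Unweighted least squares with five log-spaced IC50 starts; bottom is
    constrained >= 0.  Non-convergence is flagged, not raised.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(activity, dtype=float)
    if len(np.unique(c[c > 0])) < 5:
        raise ValueError("need >= 5 distinct positive concentrations")
    cpos = c[c > 0]
    top0 = float(np.percentile(y, 95))
    span = max(top0, 1e-12)

    def resid(p):
        lic50, hill, top, bottom = p
        return _logistic(c, np.exp(lic50), hill, top, bottom) - y

    best = None
    for lic0 in np.linspace(np.log(cpos.min()), np.log(cpos.max()), 5):
        try:
            sol = least_squares(
                resid, x0=[lic0, 1.0, top0, 0.0],
                bounds=([np.log(cpos.min()) - 14, 0.2, 0.0, 0.0],
                        [np.log(cpos.max()) + 14, 6.0, 10 * span + 1e3, span]),
                method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, False)
    lic50, hill, top, bottom = best.x
    rss = float(2 * best.cost)
    se = _param_se(best.jac, rss, len(y))
    # delta method: se(IC50) = IC50 * se(log IC50)
    return DoseResponseFit(float(np.exp(lic50)), float(hill), float(top),
                           float(bottom), float(np.exp(lic50) * se[0]),
                           float(se[1]), rss, bool(best.success))


def _param_se(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    p = jac.shape[1]
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


# ---------------------------------------------------------------------------
# Competitive Ki (global fit)
# ---------------------------------------------------------------------------

@dataclass
class CompetitiveFit:
    vmax: float
    km: float
    ki: float
    se_vmax: float
    se_km: float
    se_ki: float
    rss: float
    converged: bool

    def as_dict(self) -> dict:
        return {"vmax": self.vmax, "km": self.km, "ki": self.ki,
                "se_vmax": self.se_vmax, "se_km": self.se_km,
                "se_ki": self.se_ki, "rss": self.rss,
                "converged": self.converged}


def competitive_rate(k: np.ndarray, i: np.ndarray, vmax: float, km: float,
                     ki: float) -> np.ndarray:
    """Competitive Michaelis-Menten: v = Vmax [K] / (Km (1 + [I]/Ki) + [K])."""
    return vmax * k / (km * (1.0 + i / ki) + k)


def fit_ki_competitive(dataset: pd.DataFrame) -> CompetitiveFit:
    """Simultaneous nonlinear regression of the competitive model.

    ``dataset`` must have columns ``k_conc``, ``inhibitor_conc`` and
    ``activity`` (background-corrected); Vmax and Km are shared across all
    inhibitor levels, yielding one global Ki.  Parameters are fitted in
    log space (hence strictly positive); multi-start over Ki.
    """
    for col in ("k_conc", "inhibitor_conc", "activity"):
        if col not in dataset.columns:
            raise PlateDataError(f"dataset lacks column {col!r}")
    k = dataset["k_conc"].to_numpy(dtype=float)
    i = dataset["inhibitor_conc"].to_numpy(dtype=float)
    v = dataset["activity"].to_numpy(dtype=float)
    n_i = len(np.unique(i))
    n_k = len(np.unique(k[k > 0]))
    if n_i < 3 or 0.0 not in np.unique(i):
        raise ValueError("need >= 3 inhibitor concentrations including 0")
    if n_k < 4:
        raise ValueError("need >= 4 K+ concentrations")

    vmax0 = float(v.max()) if v.max() > 0 else 1.0
    km0 = float(np.median(k[k > 0]))
    ipos = i[i > 0]

    def resid(p):
        return competitive_rate(k, i, np.exp(p[0]), np.exp(p[1]), np.exp(p[2])) - v

    best = None
    for ki0 in np.geomspace(ipos.min() / 30.0, ipos.max() * 30.0, 7):
        try:
            sol = least_squares(resid, x0=[np.log(vmax0), np.log(km0), np.log(ki0)],
                                method="lm")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return CompetitiveFit(*([np.nan] * 6), np.nan, False)
    vmax, km, ki = np.exp(best.x)
    rss = float(2 * best.cost)
    se_log = _param_se(best.jac, rss, len(v))
    return CompetitiveFit(float(vmax), float(km), float(ki),
                          float(vmax * se_log[0]), float(km * se_log[1]),
                          float(ki * se_log[2]), rss, bool(best.success))


def ic50_from_ki(ki: float, k_conc: float, km: float) -> float:
    """Cheng-Prusoff-type relation for a K+-competitive blocker:
    IC50 = Ki (1 + [K]/Km) at fixed K+ concentration."""
    return ki * (1.0 + k_conc / km)


# ---------------------------------------------------------------------------
# Double-reciprocal diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ReciprocalSeries:
    inhibitor_conc: float
    inv_k: np.ndarray
    inv_v: np.ndarray
    slope: float
    intercept: float


def double_reciprocal(dataset: pd.DataFrame) -> List[ReciprocalSeries]:
    """Lineweaver-Burk series (1/[K+], 1/v) with per-series linear fits.

    Wells with non-positive activity or zero [K+] are excluded.  For a
    purely competitive inhibitor all series share the 1/Vmax intercept
    while slopes grow as ``(Km/Vmax) * (1 + [I]/Ki)``.
    """
    out: List[ReciprocalSeries] = []
    for ic, grp in dataset.groupby("inhibitor_conc"):
        mask = (grp["activity"] > 0) & (grp["k_conc"] > 0)
        g = grp[mask]
        if len(g) < 2:
            continue
        x = 1.0 / g["k_conc"].to_numpy(dtype=float)
        y = 1.0 / g["activity"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        out.append(ReciprocalSeries(float(ic), x, y, float(slope), float(intercept)))
    return sorted(out, key=lambda s: s.inhibitor_conc)


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

def protonation_ratio(pka: float, ph: float) -> float:
    """Protonated : neutral ratio of a basic amine (Henderson-Hasselbalch).

    Returns ``10 ** (pKa - pH)``; e.g. 0.04 (i.e. 1:25) for pKa 5.6 at
    pH 7, and 10,000 for pKa 11 at pH 7.
    """
    return float(10.0 ** (pka - ph))
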