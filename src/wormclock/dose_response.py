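"""Four-parameter logistic (4PL) dose-response fitting and EC50 reporting.

Model (variable slope, fitted on log10 concentration):

    y = floor + (ceil - floor) / (1 + 10**(hill * (log10(EC50) - log10(c))))

EC50 is the ligand concentration at half-maximal activation.  Fitting is
least squares with multi-start over a log-spaced EC50 grid spanning the
tested concentrations, which avoids plateau-dominated local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["LogisticFit", "fit_4pl", "four_pl"]


@dataclass
class LogisticFit:
    ec50_M: float
    hill: float
    floor_pct: float
    ceil_pct: float
    se_log10_ec50: float
    converged: bool
    identifiable: bool
    rss: float = np.nan

    @property
    def ec50_nM(self) -> float:
        return self.ec50_M * 1e9


def four_pl(log_c: np.ndarray, floor: float, ceil: float,
            log_ec50: float, hill: float) -> np.ndarray:
    expo = np.clip(hill * (log_ec50 - log_c), -300.0, 300.0)
    return floor + (ceil - floor) / (1.0 + 10.0 ** expo)


def fit_4pl(data: pd.DataFrame, mode: str = "replicates",
            group: str | None = "receptor") -> LogisticFit:
    """Fit the 4PL model to (concentration_M, activation_pct) data.

    ``mode='means'`` fits per-concentration means instead of replicate-level
    points.  Requires >= 4 distinct concentrations.  The fit is flagged
    non-identifiable when the EC50 confidence interval (+- 2 SE on log10
    scale) spans beyond the tested concentration range, or when the curve has
    no usable dynamic range (e.g. a flat empty-vector control).
    """
    df = data
    if group is not None and "group" in df.columns:
        df = df[df["group"] == group]
    conc = df["concentration_M"].to_numpy(float)
    y = df["activation_pct"].to_numpy(float)
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if mode == "means":
        s = df.groupby("concentration_M")["activation_pct"].mean()
        conc = s.index.to_numpy(float)
        y = s.to_numpy(float)
    elif mode != "replicates":
        raise ValueError("mode must be 'replicates' or 'means'")
    log_c = np.log10(conc)

    lo, hi = log_c.min(), log_c.max()
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    starts = []
    for le in np.linspace(lo, hi, 7):
        for hill0 in (1.0, 2.0):
            starts.append((y_lo, y_hi, le, hill0))

    def resid(theta):
        return four_pl(log_c, *theta) - y

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           converged=False, identifiable=False)
    floor, ceil, log_ec50, hill = best.x
    if ceil < floor:  # canonical orientation
        floor, ceil, hill = ceil, floor, -hill
    rss = float(2 * best.cost)
    dof = max(1, y.size - 4)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
        se_log_ec50 = float(np.sqrt(max(cov[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        se_log_ec50 = np.inf
    span = ceil - floor
    resid_sd = float(np.sqrt(sigma2))
    identifiable = bool(
        lo <= log_ec50 <= hi
        and np.isfinite(se_log_ec50)
        and (log_ec50 - 2 * se_log_ec50) >= lo - 1.0
        and (log_ec50 + 2 * se_log_ec50) <= hi + 1.0
        and span > 4 * resid_sd
    )
    return LogisticFit(
        ec50_M=float(10.0 ** log_ec50), hill=float(hill),
        floor_pct=float(floor), ceil_pct=float(ceil),
        se_log10_ec50=se_log_ec50, converged=True,
        identifiable=identifiable, rss=rss,
    )
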