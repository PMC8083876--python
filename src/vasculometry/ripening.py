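"""Constrained logistic sugar-accumulation kinetics and AIC curve sharing.

Total soluble solids (TSS, degrees Brix) as a function of days after
anthesis x is modelled as

    Y(x) = YM * Y0 / ((YM - Y0) * exp(-k x) + Y0)

with the initial level Y0 box-constrained to [0, 5] Brix, the asymptote YM
fixed at 32 Brix (optionally estimated for sensitivity analysis) and the
rate constant k (day^-1) positive.  Curve-sharing hypotheses across
cultivars (one shared curve, per-cultivar curves, or arbitrary groupings)
are compared by small-sample corrected AIC under a common-variance
least-squares formulation:

    AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n - p - 1)

where p counts the (Y0, k) pairs per group (plus YM if estimated) plus one
residual-variance parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from vasculometry.synthetic import logistic_curve

#: the constrained logistic evaluated at given parameters
logistic_tss = logistic_curve

Y0_BOUNDS = (0.0, 5.0)
YM_FIXED = 32.0
#: multistart grid for the rate constant, day^-1
K_START_GRID = tuple(np.logspace(-3, 0, 8))


@dataclass
class LogisticFit:
    """Fitted constrained logistic curve for one series or pooled group."""

    Y0: float
    YM: float
    k: float
    rss: float
    n: int
    p: int
    aicc: float
    ym_estimated: bool = False
    flags: list = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags

    def predict(self, x):
        return logistic_curve(x, self.Y0, self.YM, self.k)


def aicc_from_rss(rss: float, n: int, p: int) -> float:
    """Least-squares AICc; p includes the residual-variance parameter."""
    if n - p - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, p={p} (n - p - 1 <= 0)")
    rss = max(rss, 1e-300)  # guard log(0) on exact fits
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _fit_one(
    x: np.ndarray, y: np.ndarray, estimate_ym: bool
) -> tuple[np.ndarray, float]:
    """Bounded least squares with a log-spaced multistart over k."""

    if estimate_ym:
        lb = [Y0_BOUNDS[0] + 1e-9, 1e-6, 1e-6]
        ub = [Y0_BOUNDS[1], 5.0, 100.0]

        def resid(theta):
            return logistic_curve(x, theta[0], theta[2], theta[1]) - y

    else:
        lb = [Y0_BOUNDS[0] + 1e-9, 1e-6]
        ub = [Y0_BOUNDS[1], 5.0]

        def resid(theta):
            return logistic_curve(x, theta[0], YM_FIXED, theta[1]) - y

    y0_start = float(np.clip(y.min(), 0.5, Y0_BOUNDS[1] - 0.5))
    best = None
    for k0 in K_START_GRID:
        start = [y0_start, k0] + ([max(y.max(), YM_FIXED)] if estimate_ym else [])
        if estimate_ym:
            start[2] = float(np.clip(start[2], lb[2], ub[2]))
        try:
            sol = least_squares(resid, start, bounds=(lb, ub), method="trf")
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise RuntimeError("logistic fit failed from every start of the k grid")
    return best


def fit_logistic(
    series: pd.DataFrame, estimate_ym: bool = False
) -> LogisticFit:
    """Fit the constrained logistic to one TSS series.

    ``series`` needs columns ``daa`` and ``brix``; at least three distinct
    timepoints.  A flat series leaves k unidentifiable: the fit is returned
    with a ``degenerate`` flag rather than silently.
    """
    x = np.asarray(series["daa"], dtype=float)
    y = np.asarray(series["brix"], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct timepoints")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite TSS values")

    theta, rss = _fit_one(x, y, estimate_ym)
    n = len(y)
    p = (3 if estimate_ym else 2) + 1  # parameters + residual variance
    fit = LogisticFit(
        Y0=float(theta[0]),
        YM=float(theta[2]) if estimate_ym else YM_FIXED,
        k=float(theta[1]),
        rss=rss,
        n=n,
        p=p,
        aicc=aicc_from_rss(rss, n, p),
        ym_estimated=estimate_ym,
    )
    # unidentifiable k: response flat relative to noise, or Y0 jammed at the
    # upper bound with a vanishing rate
    if np.std(y) < 1e-9 or (
        fit.k <= 2e-6 and abs(fit.Y0 - Y0_BOUNDS[1]) < 1e-6
    ):
        fit.flags.append("degenerate")
    return fit


def _partition_label(groups: Sequence[Sequence[str]]) -> str:
    return " | ".join("+".join(sorted(g)) for g in groups)


def compare_curve_sharing(
    table: pd.DataFrame,
    partitions: Sequence[Sequence[Sequence[str]]] | None = None,
    estimate_ym: bool = False,
) -> dict:
    """Select among curve-sharing hypotheses by total AICc.

    ``table`` is a tidy frame with columns ``cultivar, daa, brix``.  The
    candidate set always includes the fully pooled partition (one curve for
    every cultivar) and the fully separate partition (one curve each);
    ``partitions`` adds user-specified groupings, each a list of cultivar
    groups covering every cultivar.

    For each candidate, each group is fitted by pooled least squares over
    its member series and the candidate is scored by AICc computed from the
    total RSS over all observations, with p = 2 parameters per group (+1 if
    YM is estimated, per group) + 1 shared variance.

    Returns a dict with ``best`` (the winning partition label), ``table``
    (a DataFrame with partition, n_groups, p, rss, aicc, delta_aicc), and
    ``fits`` mapping partition label -> list of per-group LogisticFit.
    """
    cultivars = sorted(table["cultivar"].unique())
    if len(cultivars) < 1:
        raise ValueError("no cultivars in table")

    candidates: list[list[list[str]]] = [[list(cultivars)]]
    if len(cultivars) > 1:
        candidates.append([[c] for c in cultivars])
    for part in partitions or []:
        named = sorted(c for grp in part for c in grp)
        if named != cultivars:
            unknown = set(named) - set(cultivars)
            if unknown:
                raise ValueError(f"partition names unknown cultivars: {sorted(unknown)}")
            raise ValueError("partition must cover every cultivar exactly once")
        candidates.append([list(g) for g in part])

    per_curve = 3 if estimate_ym else 2
    rows = []
    fits_by_label: dict[str, list[LogisticFit]] = {}
    for part in candidates:
        label = _partition_label(part)
        if label in fits_by_label:
            continue
        rss_total = 0.0
        n_total = 0
        fits = []
        for group in part:
            sub = table[table["cultivar"].isin(group)]
            fit = fit_logistic(sub, estimate_ym=estimate_ym)
            fits.append(fit)
            rss_total += fit.rss
            n_total += fit.n
        p = per_curve * len(part) + 1  # + common variance
        rows.append(
            {
                "partition": label,
                "n_groups": len(part),
                "p": p,
                "rss": rss_total,
                "aicc": aicc_from_rss(rss_total, n_total, p),
            }
        )
        fits_by_label[label] = fits

    result = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    result["delta_aicc"] = result["aicc"] - result["aicc"].iloc[0]
    return {
        "best": result["partition"].iloc[0],
        "table": result,
        "fits": fits_by_label,
    }
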