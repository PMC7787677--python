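"""Per-experiment (secondary) analysis of primary results.

For a titration experiment the primary stage leaves one respiration rate per
ROI in the store; this stage assembles the (concentration, rate) points and

* fits the Michaelis-Menten relationship with a basal term,
      v(c) = v0 + vmax * c / (km + c),
  by bounded nonlinear least squares (v0: basal rate at zero titrant, vmax:
  amplitude above basal, km: apparent affinity / dissociation constant);
* records minimal and maximal measured rates and the flux control ratio
      FCR = (vmax_measured - vmin) / vmax_measured,
  the ADP-stimulated fraction of the maximal flux.

Communication with the primary stage is only through the store, so secondary
results always reflect what is persisted, not an in-memory intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError
from .store import Store

__all__ = [
    "MMFit",
    "RateSummary",
    "collect_rate_points",
    "fit_michaelis_menten",
    "rate_summary",
    "analyze_secondary",
]

#: optimizer tolerance on parameters; fits are deterministic (no restarts)
_XTOL = 1e-12


@dataclass(frozen=True)
class MMFit:
    experiment_id: str
    v0: float
    vmax: float
    km: float
    rss: float
    n: int
    converged: bool

    @property
    def vtotal(self) -> float:
        """Total maximal rate v0 + vmax (saturating titrant)."""
        return self.v0 + self.vmax

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        return self.v0 + self.vmax * c / (self.km + c)


@dataclass(frozen=True)
class RateSummary:
    experiment_id: str
    vmin: float
    vmax_measured: float
    fcr: float | None


def collect_rate_points(experiment_id: str, store: Store) -> list[tuple[float, float]]:
    """Assemble (concentration mM, rate) points from persisted primary results.

    The baseline ROI contributes (0, rate); ROIs labeled with the titration
    agent contribute their parsed concentration. Unlabeled ROIs and ROIs
    labeled with a different agent are excluded. Repeated concentrations are
    kept as separate points. Ordered by concentration.
    """
    rows = store.conn.execute(
        "SELECT r.event_name, r.event_value, l.rate FROM roi AS r "
        "JOIN roi_linear AS l ON l.roi_id = r.roi_id "
        "WHERE r.experiment_id = ? AND l.status = 'ok' AND l.rate IS NOT NULL",
        (experiment_id,),
    ).fetchall()

    agents = Counter(
        name for name, value, _ in rows if value is not None and name != "baseline"
    )
    agent = agents.most_common(1)[0][0] if agents else None

    points: list[tuple[float, float]] = []
    for name, value, rate in rows:
        if name == "baseline":
            points.append((0.0, float(rate)))
        elif value is not None and name == agent:
            points.append((float(value), float(rate)))
    if not points:
        raise InsufficientDataError(
            f"experiment {experiment_id!r} has no concentration-labeled ROI rates"
        )
    points.sort(key=lambda p: p[0])
    return points


def fit_michaelis_menten(
    points: list[tuple[float, float]],
    experiment_id: str = "",
    basal: bool = True,
) -> MMFit:
    """Bounded nonlinear least squares of v(c) = v0 + vmax*c/(km + c).

    Deterministic initialization: v0 from the rate at the smallest
    concentration, vmax from the observed range, km from the median positive
    concentration. With ``basal=False`` the basal term is pinned to zero and
    the classic two-parameter law is fitted.
    """
    c = np.asarray([p[0] for p in points], dtype=float)
    v = np.asarray([p[1] for p in points], dtype=float)
    if len(points) < 3 or np.unique(c).size < 3:
        raise InsufficientDataError(
            f"Michaelis-Menten fit needs >= 3 distinct concentrations, "
            f"got {np.unique(c).size}"
        )
    if not np.any(c > 0):
        raise InsufficientDataError("need at least one positive concentration")

    v0_init = float(v[np.argmin(c)]) if basal else 0.0
    vmax_init = max(float(np.max(v)) - v0_init, 1e-6)
    km_init = float(np.median(c[c > 0]))

    if basal:
        x0 = np.array([v0_init, vmax_init, km_init])
        lower = np.array([0.0, 0.0, np.finfo(float).tiny])
        unpack = lambda x: (x[0], x[1], x[2])
    else:
        x0 = np.array([vmax_init, km_init])
        lower = np.array([0.0, np.finfo(float).tiny])
        unpack = lambda x: (0.0, x[0], x[1])

    def residuals(x):
        v0, vmax, km = unpack(x)
        return v0 + vmax * c / (km + c) - v

    sol = least_squares(
        residuals, x0, bounds=(lower, np.full_like(x0, np.inf)),
        xtol=_XTOL, ftol=_XTOL, gtol=_XTOL,
    )
    v0, vmax, km = unpack(sol.x)
    return MMFit(
        experiment_id=experiment_id,
        v0=float(v0),
        vmax=float(vmax),
        km=float(km),
        rss=float(np.sum(sol.fun**2)),
        n=len(points),
        converged=bool(sol.success),
    )


def rate_summary(
    points: list[tuple[float, float]], experiment_id: str = ""
) -> RateSummary:
    """Min/max measured rates and the flux control ratio.

    FCR = (vmax_measured - vmin)/vmax_measured; undefined (None) when the
    maximal measured rate is not positive.
    """
    if not points:
        raise InsufficientDataError("no rate points")
    rates = [p[1] for p in points]
    vmin, vmax_measured = min(rates), max(rates)
    fcr = (vmax_measured - vmin) / vmax_measured if vmax_measured > 0 else None
    return RateSummary(
        experiment_id=experiment_id,
        vmin=float(vmin),
        vmax_measured=float(vmax_measured),
        fcr=None if fcr is None else float(fcr),
    )


def analyze_secondary(
    experiment_id: str, store: Store, basal: bool = True
) -> tuple[MMFit, RateSummary]:
    """Fit the kinetics for one experiment and persist both result rows
    (replace-on-rerun, so a ROI edit followed by re-analysis is reflected)."""
    points = collect_rate_points(experiment_id, store)
    summary = rate_summary(points, experiment_id)
    fit = fit_michaelis_menten(points, experiment_id, basal=basal)
    store.write_result(
        "mm_fit",
        "experiment_id",
        experiment_id,
        {
            "v0": fit.v0,
            "vmax": fit.vmax,
            "km": fit.km,
            "rss": fit.rss,
            "n": fit.n,
            "converged": int(fit.converged),
            "status": "ok",
        },
    )
    store.write_result(
        "rate_summary",
        "experiment_id",
        experiment_id,
        {
            "vmin": summary.vmin,
            "vmax_measured": summary.vmax_measured,
            "fcr": summary.fcr,
        },
    )
    return fit, summary
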