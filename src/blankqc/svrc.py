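"""QC-based support-vector-regression correction (QC-SVRC) of within-batch drift.

Repeated LC-MS injections drift: ionisation efficiency and source cleanliness
change smoothly with run order, so a feature's intensity in identical samples
is not constant across a batch.  QC-SVRC models, per feature, intensity as a
smooth function of run order using epsilon-insensitive support vector
regression (RBF kernel) trained on reference injections, then divides the
fitted trend out:

    corrected(f, t) = area(f, t) * median(reference areas of f) / trend(f, t)

Reference injections are the leading conditioning QCs plus, by default, the
last sample injected before each blank group -- samples in the fully
conditioned state.  Hyperparameters per feature:

* ``C``    -- the median reference intensity (no search);
* ``epsilon`` -- searched over 3-10% of the median reference intensity,
  the expected instrumental precision band;
* ``gamma``   -- RBF width, searched log-uniformly over [1, 1e5].  The
  kernel is defined on run order normalised to the span of the reference
  injections, so gamma = 1 is a kernel as wide as the whole batch (a
  near-constant trend) and gamma = 1e5 bends at the scale of a single
  injection.

(epsilon, gamma) minimise the leave-one-out RMSECV over the grid; ties are
broken toward smaller gamma (smoother trend) then larger epsilon (flatter
fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _svr
from .io import PeakTable

__all__ = [
    "SvrcFit",
    "rsd",
    "select_hyperparameters",
    "fit_trend",
    "reference_orders",
    "correct_table",
]

GAMMA_RANGE = (1.0, 1e5)
EPSILON_RANGE = (0.03, 0.10)  # fraction of the reference median
MIN_REFERENCES = 4


@dataclass
class SvrcFit:
    """Per-feature QC-SVRC fit: hyperparameters, LOO error and trend."""

    feature_id: str
    C: float = np.nan
    epsilon: float = np.nan
    gamma: float = np.nan
    rmsecv: float = np.nan
    trend: np.ndarray | None = None
    corrected: bool = False
    reason: str = ""
    # non-init diagnostics
    n_references: int = field(default=0)

    def as_row(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "C": self.C,
            "epsilon": self.epsilon,
            "gamma": self.gamma,
            "rmsecv": self.rmsecv,
            "corrected_flag": self.corrected,
            "reason": self.reason,
        }


def rsd(values) -> float:
    """Percent relative standard deviation, n-1 denominator.

    Undefined (NaN) for fewer than two values or zero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return np.nan
    m = v.mean()
    if m == 0:
        return np.nan
    return 100.0 * v.std(ddof=1) / m


def epsilon_grid(median_ref: float, n_eps: int = 8) -> np.ndarray:
    lo, hi = EPSILON_RANGE
    return np.linspace(lo * median_ref, hi * median_ref, n_eps)


def gamma_grid(n_gamma: int = 26) -> np.ndarray:
    return np.logspace(np.log10(GAMMA_RANGE[0]), np.log10(GAMMA_RANGE[1]), n_gamma)


def _normalise_orders(orders, ref_orders):
    """Map run orders onto [0, 1] over the span of the references.

    The gamma search interval assumes this scale: without it every grid
    value would produce kernels far narrower than the spacing between
    reference injections.
    """
    lo, hi = float(np.min(ref_orders)), float(np.max(ref_orders))
    span = hi - lo if hi > lo else 1.0
    return (np.asarray(orders, dtype=float) - lo) / span


def _loo_rmsecv(orders, areas, C, eps, gamma) -> float:
    n = len(orders)
    err = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = _svr.svr_fit(orders[keep], areas[keep], C, eps, gamma)
        err[i] = _svr.svr_predict(model, orders[i : i + 1])[0] - areas[i]
    return float(np.sqrt(np.mean(err**2)))


def select_hyperparameters(
    qc_orders,
    qc_areas,
    n_eps: int = 8,
    n_gamma: int = 26,
) -> tuple[float, float, float, float]:
    """Select (C, epsilon, gamma, rmsecv) for one feature.

    C is fixed at the median reference intensity; (epsilon, gamma) minimise
    the leave-one-out RMSECV over the grid.  Exact ties go to the smaller
    gamma, then the larger epsilon.
    """
    areas = np.asarray(qc_areas, dtype=float)
    if len(np.asarray(qc_orders)) < MIN_REFERENCES:
        raise ValueError(
            f"need >= {MIN_REFERENCES} reference injections, got "
            f"{len(np.asarray(qc_orders))}"
        )
    orders = _normalise_orders(qc_orders, qc_orders)
    C = float(np.median(areas))
    if np.ptp(areas) == 0:  # constant reference intensities: trivial fit
        return C, 0.0, GAMMA_RANGE[0], 0.0
    best = None  # (rmsecv, gamma, -eps)
    for gamma in gamma_grid(n_gamma):
        for eps in epsilon_grid(C, n_eps):
            r = _loo_rmsecv(orders, areas, C, eps, gamma)
            key = (r, gamma, -eps)
            if best is None or key < best[0]:
                best = (key, eps, gamma, r)
    _, eps, gamma, r = best
    return C, float(eps), float(gamma), float(r)


def fit_trend(qc_orders, qc_areas, C, epsilon, gamma, eval_orders) -> np.ndarray:
    """Train epsilon-SVR on the references and evaluate at ``eval_orders``."""
    areas = np.asarray(qc_areas, dtype=float)
    if np.ptp(areas) == 0:
        return np.full(len(eval_orders), areas[0], dtype=float)
    orders = _normalise_orders(qc_orders, qc_orders)
    model = _svr.svr_fit(orders, areas, C, epsilon, gamma)
    return _svr.svr_predict(model, _normalise_orders(eval_orders, qc_orders))


def reference_orders(table: PeakTable, j: int = 1) -> pd.Index:
    """Run orders of the correction references.

    Leading QCs plus the last ``j`` samples of each cycle (the samples
    injected immediately before the next blank group, i.e. in the fully
    conditioned state).  The final cycle's trailing samples are included
    even though no blank follows them, anchoring the trend at batch end.
    """
    seq = table.sequence
    refs = list(seq.index[(seq["cycle_id"] == 0) & (seq["sample_class"] == "QC")])
    for cid, grp in seq[seq["cycle_id"] > 0].groupby("cycle_id"):
        samples = grp.index[grp["sample_class"] == "sample"]
        refs.extend(samples[-j:])
    return pd.Index(sorted(refs))


def correct_table(
    table: PeakTable,
    j: int = 1,
    n_eps: int = 8,
    n_gamma: int = 26,
    trend_floor_frac: float = 1e-6,
    trends: pd.DataFrame | None = None,
) -> tuple[PeakTable, list[SvrcFit]]:
    """Divide each feature's fitted intensity trend out of the area matrix.

    Only the area matrix is corrected; RT and width are never touched.
    Features with fewer than four positive reference areas, or whose fit
    fails, are passed through unchanged with ``corrected_flag = False``.

    Parameters
    ----------
    j : number of pre-blank samples per cycle used as references.
    trends : optional externally supplied trend matrix (features x
        injections); when given, the SVR fit is skipped and the correction
        formula is applied to these trends instead (e.g. trends from a
        different smoother, or known generating curves in simulations).
    """
    refs = reference_orders(table, j=j)
    if len(refs) == 0:
        raise ValueError("empty reference set: no leading QCs or pre-blank samples")
    all_orders = table.run_orders.to_numpy(dtype=float)
    corrected = table.copy()
    area = corrected.area
    fits: list[SvrcFit] = []
    for fid in table.feature_ids:
        row = area.loc[fid]
        ref_areas = row.loc[refs].to_numpy(dtype=float)
        pos = ref_areas > 0
        fit = SvrcFit(feature_id=fid, n_references=int(pos.sum()))
        if pos.sum() < MIN_REFERENCES:
            fit.reason = "fewer than 4 positive reference areas"
            fits.append(fit)
            continue
        ro = refs.to_numpy(dtype=float)[pos]
        ra = ref_areas[pos]
        med = float(np.median(ra))
        try:
            if trends is not None:
                trend = trends.loc[fid].to_numpy(dtype=float)
                fit.C = med
            else:
                C, eps, gamma, rmsecv = select_hyperparameters(
                    ro, ra, n_eps=n_eps, n_gamma=n_gamma
                )
                fit.C, fit.epsilon, fit.gamma, fit.rmsecv = C, eps, gamma, rmsecv
                trend = fit_trend(ro, ra, C, eps, gamma, all_orders)
        except (_svr.SvrFitError, ValueError) as exc:
            fit.reason = f"fit failed: {exc}"
            fits.append(fit)
            continue
        # guard against division by ~0; relative to the trend's own scale so
        # externally supplied (e.g. unit-scale) trends are not distorted
        floor = trend_floor_frac * float(np.median(np.abs(trend)))
        trend = np.maximum(trend, floor)
        fit.trend = trend
        fit.corrected = True
        area.loc[fid] = row.to_numpy(dtype=float) * med / trend
        fits.append(fit)
    n_bad = sum(not f.corrected for f in fits)
    if n_bad:
        warnings.warn(f"{n_bad} features passed through uncorrected", stacklevel=2)
    corrected.meta["svrc_corrected"] = True
    return corrected, fits


def fits_frame(fits: list[SvrcFit]) -> pd.DataFrame:
    """SvrcFit list as a DataFrame (export format)."""
    return pd.DataFrame([f.as_row() for f in fits]).set_index("feature_id")
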