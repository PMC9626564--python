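"""Length -> sequencing-efficiency calibration via cubic smoothing splines.

Restriction fragments of a spike-in genome (classically a lambda digest) are
equimolar, so their per-molecule read frequency as a function of length
traces the library preparation's length-efficiency curve e(L) directly.  A
cubic smoothing spline fitted to those points — penalized piecewise cubics
trading data fidelity against curvature through a smoothing parameter
p in [0, 1], where p=1 interpolates and p=0 degenerates to the least-squares
line — models the strongly unimodal curve that defeats linear baselines.
Unknown samples are then corrected fragment-by-fragment: a = f / e(L),
renormalized to percent.

Because read counts above 10 kb are fairly flat, the curve is clamped to a
plateau there; below the training range it is clamped to the boundary value
rather than extrapolated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

METHODS = ("cubic_smoothing_spline", "linear", "linear_log")

#: Auto-selection grid for the smoothing parameter, expressed as the
#: equivalent roughness penalty lam = (1-p)/p, log-spaced over 14 decades.
_LAM_GRID = np.logspace(-4, 10, 43)


def _lam_of(p: float) -> float:
    return (1.0 - p) / p


def _p_of(lam: float) -> float:
    return 1.0 / (1.0 + lam)


class SplineCalibration:
    """Estimator mapping fragment length to relative sequencing efficiency.

    Parameters
    ----------
    method
        ``"cubic_smoothing_spline"`` (default), ``"linear"`` (least-squares
        line in L) or ``"linear_log"`` (least-squares line in log L), the
        two baselines the spline is judged against.
    smooth
        Smoothing parameter p in [0, 1]; ``None`` selects p by leave-one-out
        cross-validation on the training points.  Ignored by the linear
        methods.
    plateau_length
        Length (bp) above which predicted efficiency is held constant
        (default 10,000: read counts are fairly flat beyond that).
    log_y
        Fit log efficiency instead of efficiency (back-transformed on
        predict).

    Attributes
    ----------
    spline_ : scipy.interpolate.BSpline
        Fitted curve (smoothing-spline method, p > 0).
    coef_ : ndarray of shape (2,)
        Slope/intercept of the fitted line (linear methods and p = 0).
    smooth_ : float
        The smoothing parameter actually used.
    training_range_ : tuple of float
        (L_min, L_max) of the training lengths; predictions clamp to it.
    plateau_value_ : float
        e(L) for L beyond min(plateau_length, L_max).
    """

    def __init__(
        self,
        method: str = "cubic_smoothing_spline",
        smooth: float | None = None,
        plateau_length: float = 10_000.0,
        log_y: bool = False,
    ) -> None:
        self.method = method
        self.smooth = smooth
        self.plateau_length = plateau_length
        self.log_y = log_y

    # -- sklearn-style parameter plumbing -----------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "method": self.method,
            "smooth": self.smooth,
            "plateau_length": self.plateau_length,
            "log_y": self.log_y,
        }

    def set_params(self, **params) -> "SplineCalibration":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ------------------------------------------------------------
    def _validate_xy(self, lengths, response) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(lengths, dtype=float).ravel()
        y = np.asarray(response, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("lengths and response differ in shape")
        if np.any(x <= 0):
            raise ValueError("fragment lengths must be positive")
        # smoothing-spline abscissae must be distinct: aggregate duplicate
        # lengths by mean response
        order = np.argsort(x)
        x, y = x[order], y[order]
        ux, inverse = np.unique(x, return_inverse=True)
        if len(ux) < len(x):
            uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
            x, y = ux, uy
        if self.method == "cubic_smoothing_spline" and len(x) < 5:
            # the natural-spline system is under-determined below 5 knots
            raise ValueError(f"cubic smoothing spline needs >= 5 distinct lengths, got {len(x)}")
        if len(x) < 2:
            raise ValueError("need >= 2 distinct lengths")
        return x, y

    def _fit_spline(self, x: np.ndarray, y: np.ndarray, p: float) -> None:
        if p == 0.0:
            self.coef_ = np.polyfit(x, y, 1)
            self.spline_ = None
        else:
            self.spline_ = make_smoothing_spline(x, y, lam=_lam_of(p))
            self.coef_ = None
        self.smooth_ = p

    def _loo_select(self, x: np.ndarray, y: np.ndarray) -> float:
        """Leave-one-out CV over the lam grid; returns the chosen p.

        Only interior points are scored: deleting a boundary abscissa turns
        its prediction into cubic extrapolation, whose wild variance at low
        lam would otherwise push the selection toward drastic over-smoothing.
        """
        if len(x) < 6:
            raise ValueError("automatic smoothing selection needs >= 6 distinct lengths")
        best_lam, best_err = None, np.inf
        for lam in _LAM_GRID:
            sq = 0.0
            for i in range(1, len(x) - 1):
                xm = np.delete(x, i)
                ym = np.delete(y, i)
                try:
                    spl = make_smoothing_spline(xm, ym, lam=lam)
                except Exception:
                    sq = np.inf
                    break
                sq += float(spl(x[i]) - y[i]) ** 2
            if sq < best_err:
                best_err, best_lam = sq, lam
        if best_lam is None:
            raise RuntimeError("leave-one-out selection failed on every candidate")
        return _p_of(best_lam)

    def fit(self, lengths, response) -> "SplineCalibration":
        """Fit e(L) to spike-in (length, per-molecule frequency) points."""
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        x, y = self._validate_xy(lengths, response)
        if self.log_y:
            if np.any(y <= 0):
                raise ValueError("log_y requires positive responses")
            y = np.log(y)
        if self.method == "linear":
            self.coef_ = np.polyfit(x, y, 1)
            self.spline_ = None
            self.smooth_ = None
        elif self.method == "linear_log":
            self.coef_ = np.polyfit(np.log(x), y, 1)
            self.spline_ = None
            self.smooth_ = None
        else:
            p = self.smooth if self.smooth is not None else self._loo_select(x, y)
            if not 0.0 <= p <= 1.0:
                raise ValueError("smooth must lie in [0, 1]")
            self._fit_spline(x, y, p)
        self.training_range_ = (float(x[0]), float(x[-1]))
        self.n_points_ = int(len(x))
        cap = min(self.plateau_length, self.training_range_[1])
        self.plateau_value_ = float(self._raw_predict(np.array([cap]))[0])
        return self

    # -- prediction ---------------------------------------------------------
    def _raw_predict(self, L: np.ndarray) -> np.ndarray:
        if self.method == "linear_log":
            out = np.polyval(self.coef_, np.log(L))
        elif self.spline_ is not None:
            out = self.spline_(L)
        else:
            out = np.polyval(self.coef_, L)
        return np.exp(out) if self.log_y else out

    def _check_fitted(self) -> None:
        if not hasattr(self, "training_range_"):
            raise RuntimeError("calibration model is not fitted")

    def predict(self, lengths) -> np.ndarray:
        """Predicted relative efficiency e(L), clamped outside the modeled range.

        L below the training minimum returns e(L_min); L beyond
        min(plateau_length, L_max) returns the plateau value.
        """
        self._check_fitted()
        L = np.asarray(lengths, dtype=float).ravel()
        lo, hi = self.training_range_
        cap = min(self.plateau_length, hi)
        return self._raw_predict(np.clip(L, lo, cap))

    def in_range(self, lengths) -> np.ndarray:
        self._check_fitted()
        L = np.asarray(lengths, dtype=float).ravel()
        lo, hi = self.training_range_
        return (L >= lo) & (L <= min(self.plateau_length, hi))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        state: dict = {
            "method": self.method,
            "smooth": self.smooth_ if self.method == "cubic_smoothing_spline" else None,
            "log_y": self.log_y,
            "plateau_length": self.plateau_length,
            "training_range": list(self.training_range_),
            "plateau_value": self.plateau_value_,
            "n_points": self.n_points_,
        }
        if self.spline_ is not None:
            state["spline"] = {
                "t": [float(v).hex() for v in self.spline_.t],
                "c": [float(v).hex() for v in self.spline_.c],
                "k": int(self.spline_.k),
            }
        else:
            state["coef"] = [float(v).hex() for v in self.coef_]
        return state

    @classmethod
    def from_dict(cls, state: dict) -> "SplineCalibration":
        model = cls(
            method=state["method"],
            smooth=state.get("smooth"),
            plateau_length=state["plateau_length"],
            log_y=state["log_y"],
        )
        if "spline" in state:
            spl = state["spline"]
            model.spline_ = BSpline(
                np.array([float.fromhex(v) for v in spl["t"]]),
                np.array([float.fromhex(v) for v in spl["c"]]),
                spl["k"],
            )
            model.coef_ = None
        else:
            model.coef_ = np.array([float.fromhex(v) for v in state["coef"]])
            model.spline_ = None
        model.smooth_ = state.get("smooth")
        model.training_range_ = tuple(state["training_range"])
        model.plateau_value_ = state["plateau_value"]
        model.n_points_ = state["n_points"]
        return model

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SplineCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# module-level convenience wrappers


def per_molecule_frequency(table: pd.DataFrame) -> pd.DataFrame:
    """Spike-in response: freq_pct divided by duplicate copy count.

    Collapsed duplicate fragments (copy_count > 1) receive reads from every
    copy; equimolarity holds per molecule, so the response is
    ``freq_pct / copy_count``.
    """
    df = table.copy()
    copies = df["copy_count"] if "copy_count" in df.columns else 1
    df["per_molecule_freq"] = df["freq_pct"] / copies
    return df


def fit_calibration(
    spike_table: pd.DataFrame,
    method: str = "cubic_smoothing_spline",
    smooth: float | None = None,
    min_points: int = 10,
    log_y: bool = True,
    **kwargs,
) -> SplineCalibration:
    """Fit a calibration model on a spike-in count table.

    Uses fragments with nonzero counts; requires at least ``min_points`` of
    them so the curve is constrained across the target range.  The response
    is fitted on a log scale by default: read counts carry multiplicative
    (Poisson-proportional) noise over a large dynamic range, and a linear-
    scale least-squares fit would let the high-frequency mid-length points
    dominate at the expense of the steep short-fragment flank.  Pass
    ``log_y=False`` for a linear-scale fit.
    """
    df = per_molecule_frequency(spike_table)
    df = df[df["count"] > 0] if "count" in df.columns else df[df["freq_pct"] > 0]
    if len(df) < min_points:
        raise ValueError(
            f"only {len(df)} spike-in fragments with reads; need >= {min_points}"
        )
    model = SplineCalibration(method=method, smooth=smooth, log_y=log_y, **kwargs)
    return model.fit(df["length"], df["per_molecule_freq"])


def evaluate_fit(model: SplineCalibration, holdout_table: pd.DataFrame) -> dict:
    """Goodness of fit on held-out fragments inside the training range."""
    df = per_molecule_frequency(holdout_table)
    df = df[model.in_range(df["length"])]
    if not len(df):
        raise ValueError("no holdout fragments inside the model's training range")
    pred = model.predict(df["length"])
    obs = df["per_molecule_freq"].to_numpy(dtype=float)
    resid = pred - obs
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(resid) / np.where(obs > 0, obs, np.nan)
    return {
        "n": int(len(df)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "median_abs_rel_err": float(np.nanmedian(rel)),
    }


def compare_methods(
    spike_table: pd.DataFrame,
    holdout_table: pd.DataFrame,
    smooth: float | None = None,
) -> pd.DataFrame:
    """Side-by-side goodness of fit for the spline and both linear baselines."""
    rows = []
    for method in METHODS:
        model = fit_calibration(spike_table, method=method, smooth=smooth)
        rows.append({"method": method, **evaluate_fit(model, holdout_table)})
    return pd.DataFrame(rows)


def calibrate(sample_table: pd.DataFrame, model: SplineCalibration) -> pd.DataFrame:
    """Correct a sample's frequencies into molar abundance estimates.

    ``corrected_abundance = freq_pct / e(L)``, renormalized so the corrected
    abundances sum to exactly 100.  Lengths outside the modeled range use
    the clamped efficiency and are flagged ``in_range=False``.
    """
    eff = model.predict(sample_table["length"])
    if np.any(eff <= 0):
        raise ValueError(
            "model predicts non-positive efficiency inside the clamped range; "
            "refit with more smoothing or more spike-in points"
        )
    out = sample_table[["fragment_id", "length", "freq_pct"]].copy()
    out["efficiency"] = eff
    raw = out["freq_pct"] / eff
    total = raw.sum()
    if total <= 0:
        raise ValueError("sample has no reads to calibrate")
    out["corrected_abundance"] = 100.0 * raw / total
    out["in_range"] = model.in_range(sample_table["length"])
    return out
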