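"""Guinier and Kratky analysis of small-angle X-ray scattering curves.

The Guinier approximation, I(q) ≈ I₀ exp(−q²Rg²/3), holds at low q; the
fit is a (weighted) linear regression of ln I on q² restricted to the
window q·Rg < 0.8.  Because the admissible window itself depends on Rg,
the window is found by fixed-point iteration from a deterministic initial
guess.  Forward scattering calibrated against a standard of known mass
yields the association number.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_QRG_MAX = 0.8


class GuinierFitError(RuntimeError):
    """Raised when no valid Guinier fit exists (e.g. positive slope)."""


@dataclass
class SAXSCurve:
    """A scattering curve: q (Å⁻¹, strictly ascending, > 0), intensity
    (arbitrary units) and optional 1σ uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
        if self.q.ndim != 1 or len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if len(self.q) == 0:
            raise ValueError("empty curve")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    rg_err: float
    i0_err: float
    q_window: tuple[float, float]
    n_points: int
    r_squared: float
    aggregation_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a Guinier fit needs at least 3 points")


def read_dat(path: str | os.PathLike) -> SAXSCurve:
    """Read a 2–3 column (q, I[, σ]) text file; '#' comments and commas ok.

    Rows with non-positive q or non-finite intensity are dropped (count
    reported via a warning); rows are sorted ascending in q.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].replace(",", " ").strip()
            if not line:
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue
            if len(vals) >= 2:
                rows.append(vals[:3])
    if not rows:
        raise ValueError(f"no numeric data in {path}")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"fewer than 2 usable columns in {path}")
    arr = np.array([r[:ncol] for r in rows], float)
    good = (arr[:, 0] > 0) & np.isfinite(arr[:, 1])
    if ncol >= 3:
        good &= np.isfinite(arr[:, 2]) & (arr[:, 2] > 0)
    n_dropped = int(np.count_nonzero(~good))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} invalid rows from {path}")
    arr = arr[good]
    if len(arr) == 0:
        raise ValueError(f"no valid rows in {path}")
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSCurve(q=arr[:, 0], intensity=arr[:, 1], sigma=sigma,
                     metadata={"path": os.fspath(path)})


def write_dat(curve: SAXSCurve, path: str | os.PathLike) -> None:
    """Write a curve as 3-column (or 2-column) whitespace text."""
    with open(path, "w") as fh:
        for key, val in curve.metadata.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# q intensity" + (" sigma\n" if curve.sigma is not None else "\n"))
        for i in range(len(curve)):
            cols = [f"{curve.q[i]:.8e}", f"{curve.intensity[i]:.8e}"]
            if curve.sigma is not None:
                cols.append(f"{curve.sigma[i]:.8e}")
            fh.write(" ".join(cols) + "\n")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted least squares y = a + b x; returns (a, b, a_err, b_err, r²)."""
    if w is None:
        res = stats.linregress(x, y)
        return (res.intercept, res.slope, res.intercept_stderr, res.stderr,
                res.rvalue**2)
    W = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * W
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    yhat = X @ beta
    ss_res = float(np.sum(W * (y - yhat) ** 2))
    ybar = float(np.sum(W * y) / np.sum(W))
    ss_tot = float(np.sum(W * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    errs = np.sqrt(np.diag(cov))
    return float(beta[0]), float(beta[1]), float(errs[0]), float(errs[1]), r2


def _sign_runs_flag(residuals: np.ndarray, alpha: float = 0.01) -> bool:
    """Wald–Wolfowitz runs test on residual signs; True = trend suspected.

    A long monotone drift of Guinier residuals at low q is the classic
    signature of aggregation; this is a diagnostic flag, not a rejection.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.count_nonzero(signs > 0))
    n_neg = int(np.count_nonzero(signs < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 8:
        return False
    runs = 1 + int(np.count_nonzero(np.diff(signs) != 0))
    mu = 1 + 2 * n_pos * n_neg / n
    var = 2 * n_pos * n_neg * (2 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return False
    z = (runs - mu) / math.sqrt(var)
    return bool(stats.norm.cdf(z) < alpha)  # too few runs → systematic trend


def guinier_fit(curve: SAXSCurve, qrg_max: float = DEFAULT_QRG_MAX,
                max_iter: int = 50) -> GuinierResult:
    """Guinier fit on the largest low-q window with q·Rg < `qrg_max`.

    Weighted regression of ln I on q² (weights 1/σ_lnI² with σ_lnI = σ/I)
    when uncertainties are present.  The window is found by fixed-point
    iteration starting from the first 10 points; ties between candidate
    windows are broken toward the larger one.
    """
    pos = curve.intensity > 0
    q = curve.q[pos]
    lnI = np.log(curve.intensity[pos])
    w = None
    if curve.sigma is not None:
        sig_ln = curve.sigma[pos] / curve.intensity[pos]
        w = 1.0 / sig_ln**2
    if len(q) < 3:
        raise GuinierFitError("fewer than 3 points with positive intensity")

    def fit(n_pts: int):
        x = q[:n_pts] ** 2
        y = lnI[:n_pts]
        ww = w[:n_pts] if w is not None else None
        a, b, a_err, b_err, r2 = _wls(x, y, ww)
        if b >= 0:
            raise GuinierFitError("non-negative Guinier slope (imaginary Rg)")
        rg = math.sqrt(-3.0 * b)
        return a, b, a_err, b_err, r2, rg

    n = min(10, len(q))
    seen: set[int] = set()
    for _ in range(max_iter):
        try:
            a, b, a_err, b_err, r2, rg = fit(n)
        except GuinierFitError:
            # a short noisy start window can have an indeterminate slope;
            # grow it before declaring the curve un-fittable
            if n >= len(q):
                raise
            n = min(2 * n, len(q))
            continue
        n_new = int(np.count_nonzero(q * rg <= qrg_max * (1.0 + 1e-12)))
        n_new = max(n_new, 3)
        if n_new == n:
            break
        if n_new in seen:  # 2-cycle: break the tie toward the larger window
            n = max(n, n_new)
            a, b, a_err, b_err, r2, rg = fit(n)
            break
        seen.add(n)
        n = n_new
    else:
        raise GuinierFitError("Guinier window iteration did not converge")
    # enforce the window rule exactly: shrink until max(q)·Rg is admissible
    while n > 3 and q[n - 1] * rg > qrg_max * (1.0 + 1e-6):
        n -= 1
        a, b, a_err, b_err, r2, rg = fit(n)
    if q[n - 1] * rg > qrg_max * (1.0 + 1e-6):
        raise GuinierFitError("no admissible Guinier window under the q·Rg limit")
    x = q[:n] ** 2
    residuals = lnI[:n] - (a + b * x)
    rg_err = 3.0 * b_err / (2.0 * rg)
    return GuinierResult(
        rg=rg,
        i0=math.exp(a),
        rg_err=rg_err,
        i0_err=math.exp(a) * a_err,
        q_window=(float(q[0]), float(q[n - 1])),
        n_points=n,
        r_squared=r2,
        aggregation_flag=_sign_runs_flag(residuals),
    )


def association_number(i0_sample: float, c_sample: float, i0_ref: float,
                       c_ref: float, mw_ref: float, mw_monomer: float) -> float:
    """Association number from concentration-normalized forward scattering.

    N_ass = (I₀ˢ/cˢ) / (I₀ʳ/cʳ) · MWʳ / MW_monomer with concentrations in
    mg/mL and molecular weights in Da; the reference is a standard of known
    mass (e.g. BSA).
    """
    for name, v in (("i0_sample", i0_sample), ("c_sample", c_sample),
                    ("i0_ref", i0_ref), ("c_ref", c_ref),
                    ("mw_ref", mw_ref), ("mw_monomer", mw_monomer)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    return (i0_sample / c_sample) / (i0_ref / c_ref) * mw_ref / mw_monomer


def kratky(curve: SAXSCurve) -> SAXSCurve:
    """Kratky transform: points (q, q²·I(q)); no dimensionless rescaling."""
    q2 = curve.q**2
    sigma = q2 * curve.sigma if curve.sigma is not None else None
    meta = dict(curve.metadata)
    meta["transform"] = "kratky"
    return SAXSCurve(q=curve.q, intensity=q2 * curve.intensity, sigma=sigma,
                     metadata=meta)
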