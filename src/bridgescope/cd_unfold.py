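"""Two-state chemical (urea) denaturation analysis of CD titrations.

The observed signal is modelled with the six-parameter linear-extrapolation
(Santoro–Bolen) form

    y([U]) = [ (y_f + m_f·[U]) + (y_u + m_u·[U])·K ] / (1 + K),
    K = exp( −(ΔG_H2O − m·[U]) / RT ),

where y_f, y_u are the folded/unfolded baseline intercepts, m_f, m_u their
slopes, m the denaturant dependence of the unfolding free energy
(kcal mol⁻¹ M⁻¹) and ΔG_H2O the stability extrapolated to water.  The
transition midpoint is [U]₁/₂ = ΔG_H2O/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError
from .structure_io import CdTable

__all__ = [
    "GAS_CONSTANT_KCAL",
    "UnfoldingFit",
    "model_signal",
    "fit_unfolding",
    "fraction_unfolded",
    "average_titrations",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass
class UnfoldingFit:
    """Fitted parameters of the two-state linear-extrapolation model."""

    y_f: float
    m_f: float
    y_u: float
    m_u: float
    m: float        # kcal/(mol M)
    dG_H2O: float   # kcal/mol
    temperature_K: float = 298.15
    covariance: np.ndarray | None = None

    @property
    def midpoint(self) -> float:
        """Urea concentration (M) of half-unfolding, ΔG_H2O/m."""
        return self.dG_H2O / self.m

    def standard_errors(self) -> dict[str, float]:
        if self.covariance is None:
            return {}
        names = ("y_f", "m_f", "y_u", "m_u", "m", "dG_H2O")
        se = np.sqrt(np.diag(self.covariance))
        return dict(zip(names, se.tolist()))


def _params(fit: UnfoldingFit) -> tuple[float, ...]:
    return (fit.y_f, fit.m_f, fit.y_u, fit.m_u, fit.m, fit.dG_H2O)


def model_signal(fit: UnfoldingFit, urea) -> np.ndarray:
    """Predicted CD signal at the given urea concentrations (M)."""
    return _model(np.asarray(urea, dtype=float), *_params(fit),
                  temperature_K=fit.temperature_K)


def _model(u, y_f, m_f, y_u, m_u, m, dg, temperature_K=298.15):
    rt = GAS_CONSTANT_KCAL * temperature_K
    k = np.exp(-(dg - m * u) / rt)
    return ((y_f + m_f * u) + (y_u + m_u * u) * k) / (1 + k)


def fit_unfolding(tbl: CdTable, p0: dict | None = None) -> UnfoldingFit:
    """Nonlinear least-squares fit of the six-parameter two-state model.

    Initial guesses, unless supplied, come from straight-line regressions of
    the first and last quarter of the curve (baselines) and from the
    steepest-slope point (midpoint); m starts at a generic cooperative
    value.  Non-convergence, or a fitted midpoint outside the measured
    range, raises :class:`~bridgescope.errors.FitError` carrying the best
    iterate in its message.
    """
    u = tbl.urea
    y = tbl.signal
    t = tbl.temperature_K
    n4 = max(2, len(u) // 4)
    mf0, yf0 = np.polyfit(u[:n4], y[:n4], 1)
    mu0, yu0 = np.polyfit(u[-n4:], y[-n4:], 1)
    mid0 = u[np.argmax(np.abs(np.gradient(y, u)))]
    m0 = 1.5
    guess = {"y_f": yf0, "m_f": mf0, "y_u": yu0, "m_u": mu0,
             "m": m0, "dG_H2O": m0 * mid0}
    if p0:
        guess.update(p0)
    x0 = [guess[k] for k in ("y_f", "m_f", "y_u", "m_u", "m", "dG_H2O")]

    def f(u, *theta):
        return _model(u, *theta, temperature_K=t)

    try:
        popt, pcov = curve_fit(f, u, y, p0=x0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"unfolding fit did not converge (start {x0})") from exc
    fit = UnfoldingFit(*[float(v) for v in popt], temperature_K=t, covariance=pcov)
    if not (u.min() <= fit.midpoint <= u.max()) or fit.m <= 0:
        raise FitError(
            "no transition inside the measured urea range "
            f"(midpoint {fit.midpoint:.2f} M, m {fit.m:.3f}); best iterate {popt}"
        )
    # a real transition separates the baselines at the midpoint; otherwise
    # the six-parameter model is degenerate (e.g. a straight line)
    mid = fit.midpoint
    amplitude = abs((fit.y_u + fit.m_u * mid) - (fit.y_f + fit.m_f * mid))
    span = float(y.max() - y.min())
    if span == 0 or amplitude < 0.2 * span:
        raise FitError(
            f"no resolvable transition (amplitude {amplitude:.3g} vs signal "
            f"span {span:.3g}); best iterate {popt}"
        )
    return fit


def fraction_unfolded(tbl: CdTable, fit: UnfoldingFit) -> list[tuple[float, float]]:
    """Per-point unfolded fraction f_u = (y − y_f(u)) / (y_u(u) − y_f(u)).

    Baselines are evaluated at each urea concentration; coincident
    baselines at a point are an error.
    """
    out = []
    for u, y in tbl.points:
        base_f = fit.y_f + fit.m_f * u
        base_u = fit.y_u + fit.m_u * u
        span = base_u - base_f
        if abs(span) < 1e-12:
            raise FitError(f"baselines coincide at [urea] = {u} M")
        out.append((u, (y - base_f) / span))
    return out


def average_titrations(tables: list[CdTable], n_grid: int = 0,
                       normalize: bool = False) -> CdTable:
    """Pointwise mean of replicate titrations on a common urea grid.

    Replicates are linearly interpolated onto a shared grid (the overlap of
    their ranges; ``n_grid`` points, default the median replicate length).
    With ``normalize`` the averaged curve is min–max scaled to [0, 1].
    """
    if not tables:
        raise ValueError("no titrations to average")
    lo = max(t.urea.min() for t in tables)
    hi = min(t.urea.max() for t in tables)
    if hi <= lo:
        raise ValueError("titrations do not overlap in urea range")
    n = n_grid or int(np.median([len(t.points) for t in tables]))
    grid = np.linspace(lo, hi, n)
    sig = np.mean([np.interp(grid, t.urea, t.signal) for t in tables], axis=0)
    if normalize:
        sig = (sig - sig.min()) / (sig.max() - sig.min())
    return CdTable(points=list(zip(grid, sig)),
                   temperature_K=tables[0].temperature_K)
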