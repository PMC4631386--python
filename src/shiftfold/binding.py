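"""Binding models: fast-exchange titration K_D fitting and
four-parameter-logistic dose-response fitting.

Both are exposed statsmodels-style: a model object is built from data and
``fit()`` returns a results object carrying the estimates, their
uncertainties and a ``summary()`` table.

Fast-exchange model
-------------------
Under fast exchange the observed chemical shift of each residue is the
population-weighted average of its free and bound shifts,

    delta_obs(rho) = delta_free + f_bound(P, rho P, K_D) * Delta_bound,

with one global K_D shared across residues and a per-residue bound-state
displacement Delta_bound. Because the protein concentration (55 uM) is
comparable to K_D, the bound fraction comes from the exact single-site
mass balance with ligand depletion (quadratic), not the L >> P
approximation.

Dose-response model
-------------------
The four-parameter logistic

    y = m1 + (m2 - m1) / (1 + (x / m3)^m4)

gives y(0) = m2 and y(inf) = m1 for m4 > 0; m3 is the inflection
(half-maximal) concentration, read out as K_D in direct-binding format or
IC50 in competition format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import PlateTable

__all__ = [
    "fraction_bound", "four_pl", "FastExchangeTitration",
    "FastExchangeResults", "FourPL", "FourPLResults", "BindingFitResult",
    "FourPLFit", "fit_kd_fast_exchange", "fit_4pl", "ic50_from_fit",
]


def fraction_bound(p: float, l: float, kd: float):
    """Bound protein fraction under single-site binding with depletion.

    f = ((P + L + K_D) - sqrt((P + L + K_D)^2 - 4 P L)) / (2 P), in [0, 1].
    Vectorized over `l`.
    """
    if p <= 0 or kd <= 0:
        raise ValueError("P and K_D must be > 0")
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("L must be >= 0")
    s = p + l + kd
    f = (s - np.sqrt(s * s - 4.0 * p * l)) / (2.0 * p)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def four_pl(x, m1, m2, m3, m4):
    """Four-parameter logistic y = m1 + (m2 - m1)/(1 + (x/m3)^m4);
    y(0) = m2, y(inf) = m1 (for m4 > 0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.where(x > 0, (x / m3) ** m4, 0.0)
    y = m1 + (m2 - m1) / (1.0 + t)
    return float(y) if y.ndim == 0 else y


# ---------------------------------------------------------------------------
# fast-exchange K_D model
# ---------------------------------------------------------------------------

@dataclass
class BindingFitResult:
    """Plain record of a fast-exchange fit (K_D and per-residue bound
    shifts); `FastExchangeResults` wraps it with diagnostics."""

    kd: float                                   # molar
    per_residue_bound_shift: dict[int, tuple[float, float]]  # ppm (dH, dN)
    residual_rms: float                         # ppm
    converged: bool


class FastExchangeTitration:
    """Fast-exchange single-site titration model.

    Parameters
    ----------
    trajectories : dict[int, ndarray]
        Per-residue observed (1H, 15N) shifts, shape (n_ratios, 2), in ppm,
        ordered like `ratios`.
    protein_conc : float
        Protein concentration P in molar.
    ratios : sequence of float
        Ligand:protein molar ratios; must include 0 (the free reference).
    """

    #: residues whose total displacement is below this multiple of the
    #: noise floor are excluded from the global fit (identifiability guard)
    MIN_SHIFT_SNR = 3.0

    def __init__(self, trajectories: dict[int, np.ndarray],
                 protein_conc: float, ratios):
        self.ratios = np.asarray(ratios, dtype=float)
        if len(self.ratios) < 3 or 0.0 not in self.ratios:
            raise ValueError("need >= 3 ratios including 0")
        if not trajectories:
            raise ValueError("need at least one residue trajectory")
        self.protein_conc = float(protein_conc)
        self.trajectories = {
            int(r): np.asarray(t, dtype=float) for r, t in trajectories.items()}
        for r, t in self.trajectories.items():
            if t.shape != (len(self.ratios), 2):
                raise ValueError(f"residue {r}: trajectory shape {t.shape} "
                                 f"!= ({len(self.ratios)}, 2)")

    @classmethod
    def from_peak_tables(cls, tables, protein_conc: float,
                         ratios=None) -> "FastExchangeTitration":
        """Build from assigned peak tables (one per titration point)."""
        tables = sorted(tables, key=lambda t: t.ratio_label)
        if ratios is None:
            ratios = [t.ratio_label for t in tables]
        common = set(tables[0].by_residue())
        for t in tables[1:]:
            common &= set(t.by_residue())
        traj = {}
        for res in sorted(common):
            traj[res] = np.array([[t.by_residue()[res].h_shift,
                                   t.by_residue()[res].n_shift]
                                  for t in tables])
        return cls(traj, protein_conc, ratios)

    # -- internals ----------------------------------------------------------

    def _design(self, noise_floor: float):
        """Displacement matrix (residues kept by the SNR guard)."""
        keep, disp = [], []
        for res, t in sorted(self.trajectories.items()):
            delta = t - t[0]
            if np.abs(delta).max() >= self.MIN_SHIFT_SNR * noise_floor:
                keep.append(res)
                disp.append(delta)
        return keep, np.array(disp)  # (n_res, n_ratios, 2)

    def _residuals(self, kd, disp):
        """Profiled residuals: per-residue bound shifts solved linearly."""
        fb = fraction_bound(self.protein_conc,
                            self.ratios * self.protein_conc, kd)
        denom = float(fb @ fb)
        if denom == 0.0:
            return disp.ravel(), np.zeros(disp.shape[::2])
        amp = np.einsum("r,irk->ik", fb, disp) / denom   # (n_res, 2)
        model = amp[:, None, :] * fb[None, :, None]
        return (disp - model).ravel(), amp

    def fit(self, noise_floor: float = 1e-4,
            n_starts: int = 8) -> "FastExchangeResults":
        """Least-squares fit with a global K_D (profiled per-residue
        amplitudes; `n_starts` log-spaced K_D starting values)."""
        keep, disp = self._design(noise_floor)
        if not keep:
            return FastExchangeResults(
                model=self, kd=np.nan, kd_stderr=np.nan, bound_shifts={},
                residual_rms=np.nan, converged=False, fitted_residues=[])
        p = self.protein_conc
        best = None
        for kd0 in np.geomspace(p / 100.0, p * 100.0, n_starts):
            sol = least_squares(
                lambda lk: self._residuals(np.exp(lk[0]), disp)[0],
                x0=[np.log(kd0)], method="lm", xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        kd = float(np.exp(best.x[0]))
        resid, amp = self._residuals(kd, disp)
        dof = max(1, resid.size - (1 + 2 * len(keep)))
        rms = float(np.sqrt(np.mean(resid ** 2)))
        # delta-method standard error on log K_D from the 1D profile
        jac = np.atleast_2d(best.jac)
        jtj = float((jac * jac).sum())
        var_log = (2 * best.cost / dof) / jtj if jtj > 0 else np.inf
        kd_stderr = kd * float(np.sqrt(var_log))
        converged = bool(best.success) and np.isfinite(kd)
        shifts = {res: (float(a[0]), float(a[1])) for res, a in zip(keep, amp)}
        return FastExchangeResults(
            model=self, kd=kd, kd_stderr=kd_stderr, bound_shifts=shifts,
            residual_rms=rms, converged=converged, fitted_residues=keep)


@dataclass
class FastExchangeResults:
    """Results of a fast-exchange titration fit."""

    model: FastExchangeTitration
    kd: float
    kd_stderr: float
    bound_shifts: dict[int, tuple[float, float]]
    residual_rms: float
    converged: bool
    fitted_residues: list[int] = field(default_factory=list)

    @property
    def kd_confint(self) -> tuple[float, float]:
        """Approximate 95% interval on K_D (log-scale delta method)."""
        if not np.isfinite(self.kd_stderr) or self.kd == 0:
            return (np.nan, np.nan)
        rel = 1.96 * self.kd_stderr / self.kd
        return (self.kd * np.exp(-rel), self.kd * np.exp(rel))

    def as_record(self) -> BindingFitResult:
        return BindingFitResult(self.kd, dict(self.bound_shifts),
                                self.residual_rms, self.converged)

    def predict(self, residue: int, ratios=None) -> np.ndarray:
        """Model shifts (free + f_bound * bound displacement) for one residue."""
        m = self.model
        ratios = m.ratios if ratios is None else np.asarray(ratios, float)
        fb = fraction_bound(m.protein_conc, ratios * m.protein_conc, self.kd)
        free = m.trajectories[residue][0]
        return free[None, :] + np.outer(fb, self.bound_shifts[residue])

    def summary(self) -> str:
        lo, hi = self.kd_confint
        lines = [
            "Fast-exchange titration fit",
            "===========================",
            f"residues fitted      {len(self.fitted_residues)}",
            f"ratios               {', '.join(f'{r:g}' for r in self.model.ratios)}",
            f"P (protein)          {self.model.protein_conc * 1e6:.1f} uM",
            f"K_D                  {self.kd * 1e6:.2f} uM",
            f"95% CI               [{lo * 1e6:.2f}, {hi * 1e6:.2f}] uM",
            f"residual rms         {self.residual_rms:.5f} ppm",
            f"converged            {self.converged}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# four-parameter logistic
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    """Plain record of a 4PL fit."""

    m1: float
    m2: float
    m3: float
    m4: float
    residual_rms: float
    converged: bool = True
    descending: bool | None = None

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.m1, self.m2, self.m3, self.m4)


class FourPL:
    """Four-parameter logistic dose-response model for plate data."""

    def __init__(self, concentrations, signals):
        self.x = np.asarray(concentrations, dtype=float)
        self.y = np.asarray(signals, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("concentration/signal length mismatch")
        if len(np.unique(self.x)) < 5:
            raise ValueError("need >= 5 distinct concentrations")

    @classmethod
    def from_plate(cls, plate: PlateTable) -> "FourPL":
        return cls(plate.concentrations, plate.signals)

    def fit(self, n_starts: int = 8) -> "FourPLResults":
        x, y = self.x, self.y
        span = y.max() - y.min()
        if span < 1e-12 * max(1.0, abs(y).max()):
            return FourPLResults(model=self,
                                 fit=FourPLFit(np.nan, np.nan, np.nan, np.nan,
                                               np.nan, converged=False),
                                 stderr=(np.nan,) * 4)
        pos = x[x > 0]
        m3_grid = np.geomspace(pos.min(), pos.max(), n_starts)
        y0 = y[np.argmin(x)]
        yinf = y[np.argmax(x)]
        best = None
        for m3_0 in m3_grid:
            theta0 = [yinf, y0, np.log(m3_0), 1.0]
            sol = least_squares(self._resid, theta0, method="lm",
                                xtol=1e-15, ftol=1e-15, max_nfev=5000)
            if best is None or sol.cost < best.cost:
                best = sol
        m1, m2, logm3, m4 = best.x
        resid = best.fun
        dof = max(1, len(y) - 4)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * (2 * best.cost / dof)
            se = np.sqrt(np.diag(cov))
            stderr = (float(se[0]), float(se[1]),
                      float(np.exp(logm3) * se[2]), float(se[3]))
        except np.linalg.LinAlgError:
            stderr = (np.nan,) * 4
        fitres = FourPLFit(float(m1), float(m2), float(np.exp(logm3)),
                           float(m4), rms, converged=bool(best.success),
                           descending=bool(m2 > m1))
        return FourPLResults(model=self, fit=fitres, stderr=stderr)

    def _resid(self, theta):
        m1, m2, logm3, m4 = theta
        return four_pl(self.x, m1, m2, np.exp(logm3), m4) - self.y


@dataclass
class FourPLResults:
    """Results of a 4PL fit; `ic50` is valid for the competition format."""

    model: FourPL
    fit: FourPLFit
    stderr: tuple

    def __getattr__(self, name):
        if name in ("m1", "m2", "m3", "m4", "residual_rms", "converged",
                    "descending", "params"):
            return getattr(self.fit, name)
        raise AttributeError(name)

    def predict(self, x) -> np.ndarray:
        return four_pl(x, *self.fit.params)

    @property
    def ic50(self) -> float:
        return ic50_from_fit(self.fit)

    def summary(self) -> str:
        f = self.fit
        kind = "descending (competition)" if f.descending else "ascending (direct)"
        lines = [
            "Four-parameter logistic fit",
            "===========================",
            f"curve                {kind}",
            f"m1 (plateau, x=inf)  {f.m1:.4g} +- {self.stderr[0]:.2g}",
            f"m2 (baseline, x=0)   {f.m2:.4g} +- {self.stderr[1]:.2g}",
            f"m3 (inflection)      {f.m3:.4g} M +- {self.stderr[2]:.2g}",
            f"m4 (Hill slope)      {f.m4:.4g} +- {self.stderr[3]:.2g}",
            f"residual rms         {f.residual_rms:.4g}",
            f"converged            {f.converged}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_kd_fast_exchange(trajectories, protein_conc, ratios,
                         noise_floor: float = 1e-4) -> FastExchangeResults:
    """Fit a global K_D to per-residue shift trajectories (see
    `FastExchangeTitration`)."""
    return FastExchangeTitration(trajectories, protein_conc,
                                 ratios).fit(noise_floor=noise_floor)


def fit_4pl(plate: PlateTable) -> FourPLResults:
    """Fit the four-parameter logistic to a plate table."""
    return FourPL.from_plate(plate).fit()


def ic50_from_fit(fit, competition: bool = True) -> float:
    """Half-maximal displacement concentration of a fitted descending
    competition curve (= m3). Raises on an ascending curve when the
    competition flag is set."""
    descending = getattr(fit, "descending", None)
    if competition and descending is False:
        raise ValueError("curve is ascending; not a competition experiment")
    return float(fit.m3)
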