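"""pH titration and kinetics fits.

Occupancy-vs-pH data follow a single-pKa logistic (Henderson-Hasselbalch):
the ratio of the two protonation-linked conformers is 10^(pH - pKa), so

    Occ(pH) = base + amp / (1 + 10^(s * (pH - pKa))),  s in {+1, -1}.

The sign s (which conformer the protonated state favors) is *fitted*, not
assumed: the printed form of the equation has the ratio increasing with pH,
but occupancy data may run the other way, so both orientations are tried and
the lower residual sum wins.

Rate-vs-pH profiles use the two-pKa bell

    v(pH) = vmax / ((1 + 10^(pKa_rise - pH)) * (1 + 10^(pH - pKa_fall))),

whose analytic maximum sits at the midpoint of the two pKas.

Free-energy differences between conformers come from occupancy ratios via
dG = -R T ln(n2 / n1) (reported in kJ/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

R_GAS = 8.314  # J / (mol K)


@dataclass
class TitrationSeries:
    """(pH, value +/- sd) observations; kind is "occupancy" or "rate"."""

    ph: np.ndarray
    y: np.ndarray
    sd: np.ndarray | None = None
    kind: str = "occupancy"

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if len(self.sd) != len(self.ph):
                raise ValueError("sd length mismatch")
        if len(self.ph) != len(self.y):
            raise ValueError("ph/y length mismatch")
        if self.kind == "occupancy" and (
                (self.y < -1e-9).any() or (self.y > 1 + 1e-9).any()):
            raise ValueError("occupancies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ph)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"pH": self.ph, self.kind: self.y,
                      "sd": np.zeros(len(self)) if self.sd is None else self.sd}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "occupancy") -> "TitrationSeries":
        import pandas as pd
        df = pd.read_csv(path)
        ycol = kind if kind in df.columns else df.columns[1]
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["pH"].to_numpy(), df[ycol].to_numpy(), sd=sd, kind=kind)


def hh_logistic(ph, pka: float, base: float = 0.0, amp: float = 1.0,
                sign: float = 1.0) -> np.ndarray:
    """Henderson-Hasselbalch occupancy curve."""
    return base + amp / (1.0 + 10.0 ** (sign * (np.asarray(ph, float) - pka)))


@dataclass
class PkaFit:
    pka: float
    direction: int          # +1: protonated state favored (occ falls with pH)
    amplitude: float
    baseline: float
    ci: tuple | None = None
    residuals: np.ndarray | None = None
    ok: bool = True
    sse: float = float("nan")


def _fit_one_sign(ph, y, sign, sd=None):
    pka0 = float(ph[np.argmin(np.abs(y - (y.min() + y.max()) / 2.0))])
    span = float(np.clip(y.max() - y.min(), 1e-3, 1.0))
    base0 = float(np.clip(y.min(), 0.0, 1.0))
    lo = [ph.min() - 2.0, 0.0, 0.0]
    hi = [ph.max() + 2.0, 1.0, 1.0]
    p0 = [np.clip(pka0, lo[0], hi[0]), base0, span]

    def f(x, pka, base, amp):
        return hh_logistic(x, pka, base, amp, sign)

    popt, _ = curve_fit(f, ph, y, p0=p0, bounds=(lo, hi), sigma=sd,
                        maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    resid = y - f(ph, *popt)
    return popt, float(np.sum(resid ** 2)), resid


def fit_pka(t: TitrationSeries, n_boot: int = 1000, seed: int = 0) -> PkaFit:
    """Least-squares Henderson-Hasselbalch fit with fitted direction.

    Both signs of the exponent are tried; the orientation with the lower
    residual sum is kept.  The confidence interval is a seeded bootstrap over
    point resampling.  If a constant model beats the sigmoid on AIC the fit
    is returned with ``ok=False`` rather than raising.
    """
    if t.kind != "occupancy":
        raise ValueError("fit_pka expects an occupancy series")
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    ph, y = t.ph, t.y
    results = {}
    for sign in (+1, -1):
        try:
            results[sign] = _fit_one_sign(ph, y, sign)
        except RuntimeError:
            pass
    if not results:
        return PkaFit(float("nan"), 0, float("nan"), float("nan"), ok=False)
    sign = min(results, key=lambda s: results[s][1])
    popt, sse, resid = results[sign]
    n, k = len(ph), 3
    sse_const = float(np.sum((y - y.mean()) ** 2))
    aic_model = n * np.log(max(sse, 1e-300) / n) + 2 * k
    aic_const = n * np.log(max(sse_const, 1e-300) / n) + 2 * 1
    ok = aic_model < aic_const
    ci = None
    if n_boot > 0 and ok:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(ph[idx])) < 4:
                continue
            try:
                bopt, _, _ = _fit_one_sign(ph[idx], y[idx], sign)
                boots.append(bopt[0])
            except RuntimeError:
                continue
        if len(boots) >= 20:
            lo_q, hi_q = np.percentile(boots, [2.5, 97.5])
            ci = (float(min(lo_q, popt[0])), float(max(hi_q, popt[0])))
    return PkaFit(pka=float(popt[0]), direction=sign, amplitude=float(popt[2]),
                  baseline=float(popt[1]), ci=ci, residuals=resid, ok=ok,
                  sse=sse)


# --------------------------------------------------------------------------- #
# Bell-shaped pH-rate profile

def bell_curve(ph, pka_rise: float, pka_fall: float, vmax: float) -> np.ndarray:
    ph = np.asarray(ph, dtype=float)
    return vmax / ((1.0 + 10.0 ** (pka_rise - ph)) *
                   (1.0 + 10.0 ** (ph - pka_fall)))


@dataclass
class BellFit:
    pka_rise: float
    pka_fall: float
    optimum: float
    vmax: float
    residuals: np.ndarray | None = None
    ok: bool = True
    sse: float = float("nan")


def fit_ph_rate(t: TitrationSeries) -> BellFit:
    """Fit the two-pKa bell to a rate-vs-pH series.

    The reported optimum is the analytic maximum of the fitted curve (the
    midpoint of the two pKas for this functional form).
    """
    if t.kind != "rate":
        raise ValueError("fit_ph_rate expects a rate series")
    if len(t) < 6:
        raise ValueError("need at least 6 points")
    ph, y = t.ph, t.y
    imax = int(np.argmax(y))
    p0 = [ph[imax] - 1.0, ph[imax] + 1.0, max(y.max(), 1e-6) * 1.2]
    lo = [ph.min() - 4.0, ph.min() - 4.0, 0.0]
    hi = [ph.max() + 4.0, ph.max() + 4.0, np.inf]
    try:
        popt, _ = curve_fit(bell_curve, ph, y, p0=p0, bounds=(lo, hi),
                            sigma=t.sd, maxfev=20000, xtol=1e-14, ftol=1e-14,
                            gtol=1e-14)
    except RuntimeError:
        return BellFit(*[float("nan")] * 4, ok=False)
    resid = y - bell_curve(ph, *popt)
    sse = float(np.sum(resid ** 2))
    sse_const = float(np.sum((y - y.mean()) ** 2))
    n = len(ph)
    ok = n * np.log(max(sse, 1e-300) / n) + 6 < \
        n * np.log(max(sse_const, 1e-300) / n) + 2
    rise, fall = sorted(popt[:2])
    return BellFit(pka_rise=float(rise), pka_fall=float(fall),
                   optimum=float((rise + fall) / 2.0), vmax=float(popt[2]),
                   residuals=resid, ok=ok, sse=sse)


# --------------------------------------------------------------------------- #
# Scalar conversions

def delta_g(n1: float, n2: float, temperature: float = 298.0) -> float:
    """Free-energy difference -R T ln(n2/n1) between two conformers, kJ/mol.

    Positive when conformer 2 is the minority (n2 < n1).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("occupancies must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * temperature * np.log(n2 / n1) / 1000.0


def slope_to_rate(slope: float, epsilon: float = 1.33e4,
                  path: float = 1.0) -> float:
    """Absorbance slope (A/s) to product formation rate in uM/s
    via Beer-Lambert: rate = slope / (epsilon * path) * 1e6."""
    if epsilon <= 0 or path <= 0:
        raise ValueError("epsilon and path must be positive")
    return slope / (epsilon * path) * 1e6
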