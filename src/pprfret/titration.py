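"""Ensemble FRET titration fitting: 1:1 binding with ligand depletion.

With sensor (labeled protein) concentration S comparable to the
dissociation constant, the free-ligand approximation fails and the bound
sensor fraction follows the quadratic mass-balance solution

    fb(L) = ((Kd + S + L) - sqrt((Kd + S + L)^2 - 4 S L)) / (2 S).

Observed FRET is fret_free + fb * (fret_bound - fret_free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TitrationCurve", "TitrationFit", "bound_fraction", "fit_kd"]


def bound_fraction(ligand_conc, kd: float, sensor_conc: float):
    """Bound sensor fraction under the quadratic-depletion isotherm.

    Concentrations in nM. Vectorized over ``ligand_conc``.
    """
    L = np.asarray(ligand_conc, dtype=float)
    S = float(sensor_conc)
    b = kd + S + L
    disc = b * b - 4.0 * S * L
    # exact algebra keeps disc >= (kd + |S-L|)^2 >= 0; clip guards round-off
    assert np.all(disc > -1e-9 * np.maximum(b * b, 1.0)), "negative discriminant"
    return (b - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * S)


@dataclass
class TitrationCurve:
    """Concentration series with observed ensemble FRET."""

    ligand_concs: np.ndarray  # nM
    observed_fret: np.ndarray
    sensor_conc: float  # nM

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.observed_fret = np.asarray(self.observed_fret, dtype=float)
        if len(self.ligand_concs) != len(self.observed_fret):
            raise ValueError("concentration and FRET arrays differ in length")
        if np.any(self.ligand_concs <= 0):
            raise ValueError("ligand concentrations must be > 0")


@dataclass
class TitrationFit:
    kd: float  # nM
    fret_free: float
    fret_bound: float
    kd_se: float
    fret_free_se: float
    fret_bound_se: float
    converged: bool
    identifiable: bool
    near_stoichiometric: bool = False  # Kd << sensor conc: titration limited by depletion

    def predict(self, ligand_conc, sensor_conc: float) -> np.ndarray:
        fb = bound_fraction(ligand_conc, self.kd, sensor_conc)
        return self.fret_free + fb * (self.fret_bound - self.fret_free)


def fit_kd(curve: TitrationCurve) -> TitrationFit:
    """Nonlinear least squares of observed FRET against the depletion isotherm.

    Returns (kd, fret_free, fret_bound) with standard errors from the
    Jacobian. A flat curve or a Kd beyond 10x the sampled concentration
    range is flagged non-identifiable rather than raising.
    """
    if len(curve.ligand_concs) < 5:
        raise ValueError("need >= 5 concentrations spanning the transition")
    L = curve.ligand_concs
    y = curve.observed_fret
    S = curve.sensor_conc

    def model(Lx, kd, f0, f1):
        return f0 + bound_fraction(Lx, kd, S) * (f1 - f0)

    span = float(y.max() - y.min())
    if span < 1e-12:
        return TitrationFit(np.nan, float(y.mean()), float(y.mean()),
                            np.nan, np.nan, np.nan, False, False)
    # initial Kd: concentration at half-saturation
    half = y.min() + 0.5 * span
    kd0 = float(np.interp(half, y[np.argsort(L)], np.sort(L)))
    kd0 = min(max(kd0, L.min()), L.max())
    p0 = [kd0, float(y.min()), float(y.max())]
    try:
        popt, pcov = curve_fit(
            model, L, y, p0=p0,
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return TitrationFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, False)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    kd, f0, f1 = (float(v) for v in popt)
    identifiable = bool(kd <= 10.0 * L.max())
    return TitrationFit(
        kd=kd, fret_free=f0, fret_bound=f1,
        kd_se=float(ses[0]), fret_free_se=float(ses[1]), fret_bound_se=float(ses[2]),
        converged=converged, identifiable=identifiable,
        near_stoichiometric=bool(kd < 0.01 * S),
    )
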