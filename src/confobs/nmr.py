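"""Solution observables: PFG-NMR diffusion, CPMG relaxation, hydrodynamic
radii, binding stoichiometry, SE-HPLC calibration and mean residue
ellipticity.

Diffusion coefficients come from Stejskal-Tanner fits of pulsed-field-
gradient (PFG/DOSY) decays, I(g) = I0 * sum_j f_j exp(-D_j * k(g)) with
attenuation kernel k(g) = sigma * gamma^2 g^2 delta^2 (Delta - delta/3).
``sigma`` is the gradient shape factor; the default (2/pi)^2 corresponds
to half-sine-shaped gradient pulses. Because hydrodynamic radii are taken
as a *ratio* to an internal 1,4-dioxane reference (Stokes-Einstein:
R_H = R_H,ref * D_ref / D), the absolute gradient calibration, gamma and
sigma all cancel and never affect R_H.

Transverse relaxation is a monoexponential fit I(t) = I0 exp(-t/T2) over
a CPMG echo-delay series; R2 = 1/T2 is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: proton gyromagnetic ratio, rad s^-1 T^-1 (used when gradients are physical)
GAMMA_1H = 2.6752218744e8

#: gradient shape factor for half-sine pulses
HALF_SINE_SHAPE = (2.0 / np.pi) ** 2

#: hydrodynamic radius of the 1,4-dioxane internal reference, Angstrom
RH_DIOXANE_A = 2.12

#: SE-HPLC calibration stops being linear past this elution volume, mL
SEHPLC_LINEAR_LIMIT_ML = 3.8


class FitError(RuntimeError):
    """A decay fit failed to converge or the decay is degenerate."""


@dataclass
class DecayCurve:
    """Signal-decay series: PFG (intensity vs gradient) or CPMG (vs delay).

    ``delta`` (gradient pulse duration) and ``big_delta`` (diffusion time)
    are in seconds and required for ``kind='pfg'``.
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: str  # 'pfg' | 'cpmg'
    delta: float | None = None
    big_delta: float | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in ("pfg", "cpmg"):
            raise ValueError(f"unknown decay kind {self.kind!r}")
        if self.abscissa.size < 4:
            raise ValueError("decay needs at least 4 points")
        if self.abscissa.shape != self.intensity.shape:
            raise ValueError("abscissa and intensity lengths differ")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.kind == "pfg" and (self.delta is None or self.big_delta is None):
            raise ValueError("pfg decay requires delta and big_delta")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"abscissa": self.abscissa, "intensity": self.intensity})


@dataclass
class PeakTable:
    """Integrated peak areas of well-resolved regions, one row per region.

    Columns: ``species`` (peptide|ligand), ``region``, ``area``,
    ``protons_per_molecule``.
    """

    rows: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"species", "region", "area", "protons_per_molecule"}
        missing = need - set(self.rows.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if (self.rows["area"] < 0).any():
            raise ValueError("areas must be non-negative")
        if (self.rows["protons_per_molecule"] < 1).any():
            raise ValueError("protons_per_molecule must be >= 1")


@dataclass
class DiffusionFit:
    """Stejskal-Tanner fit result. ``d`` lists components ordered by
    decreasing D; ``fractions`` sum to 1."""

    d: np.ndarray
    i0: float
    fractions: np.ndarray
    residual: float
    n_components: int
    well_conditioned: bool = True
    rh_angstrom: float | None = None

    @property
    def d_main(self) -> float:
        """D of the dominant component."""
        return float(self.d[int(np.argmax(self.fractions))])


@dataclass
class RelaxationFit:
    t2: float
    i0: float
    residual: float

    @property
    def r2(self) -> float:
        """Transverse relaxation rate, exactly 1/T2."""
        return 1.0 / self.t2


@dataclass
class CalibrationModel:
    """Linear SE-HPLC calibration: log10(R_H/A) = intercept + slope * V."""

    slope: float
    intercept: float
    volume_range_ml: tuple[float, float]


def st_kernel(
    g: np.ndarray,
    delta: float,
    big_delta: float,
    gamma: float = GAMMA_1H,
    shape_factor: float = HALF_SINE_SHAPE,
) -> np.ndarray:
    """Stejskal-Tanner attenuation factor k(g) = sigma*gamma^2 g^2 delta^2 (Delta - delta/3).

    Exponent of the decay is -D * k(g). Units must be mutually consistent;
    with g in T/m and times in s, D is in m^2/s.
    """
    g = np.asarray(g, dtype=float)
    return shape_factor * gamma**2 * g**2 * delta**2 * (big_delta - delta / 3.0)


def fit_stejskal_tanner(
    decay: DecayCurve,
    n_components: int = 1,
    gamma: float = GAMMA_1H,
    shape_factor: float = HALF_SINE_SHAPE,
) -> DiffusionFit:
    """Fit a mono- or bi-exponential Stejskal-Tanner decay.

    Multi-start nonlinear least squares (three log-spaced D starts seeded
    from the log-linear slope estimate); for ``n_components=2`` the
    components are reported ordered by decreasing D.
    """
    if decay.kind != "pfg":
        raise ValueError("fit_stejskal_tanner expects a pfg decay")
    if n_components not in (1, 2):
        raise FitError("only 1- or 2-component fits are supported")
    k = st_kernel(decay.abscissa, decay.delta, decay.big_delta, gamma, shape_factor)
    y = decay.intensity
    i0_guess = float(np.max(y))
    # slope of ln(I) vs k gives a starting D; guard degenerate decays
    pos = y > 0
    if pos.sum() < 3 or np.ptp(y) == 0:
        raise FitError("degenerate decay: intensity carries no attenuation")
    slope = -np.polyfit(k[pos], np.log(y[pos]), 1)[0]
    d_guess = max(slope, 1e-30)

    def resid_1(p):
        i0, logd = p
        return i0 * np.exp(-np.exp(logd) * k) - y

    def resid_2(p):
        i0, logd1, logd2, logit_f = p
        f = 1.0 / (1.0 + np.exp(-logit_f))
        model = i0 * (f * np.exp(-np.exp(logd1) * k) + (1 - f) * np.exp(-np.exp(logd2) * k))
        return model - y

    starts: list[list[float]]
    if n_components == 1:
        starts = [[i0_guess, np.log(d_guess * m)] for m in (0.3, 1.0, 3.0)]
    else:
        # peel: slow D from the tail slope, fast D from the early residual
        tail = k >= np.median(k)
        d_slow0 = max(-np.polyfit(k[tail & pos], np.log(y[tail & pos]), 1)[0], 1e-30)
        head = k <= np.quantile(k, 0.3)
        resid0 = y[head & pos] - i0_guess * 0.9 * np.exp(-d_slow0 * k[head & pos])
        d_fast0 = 10.0 * d_slow0
        if np.any(resid0 > 0):
            kk = k[head & pos][resid0 > 0]
            d_fast0 = max(-np.polyfit(kk, np.log(resid0[resid0 > 0]), 1)[0], 2 * d_slow0)
        starts = [
            [i0_guess, np.log(d_fast0), np.log(d_slow0), np.log(1 / 9)],  # f ~ 0.1
            [i0_guess, np.log(d_guess * 3), np.log(d_guess / 3), 0.0],
            [i0_guess, np.log(d_guess * 10), np.log(d_guess), -2.0],
            [i0_guess, np.log(d_guess), np.log(d_guess / 10), 2.0],
        ]
    best = None
    for x0 in starts:
        sol = optimize.least_squares(resid_1 if n_components == 1 else resid_2, x0)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError(f"diffusion fit did not converge (residual {best.cost if best else 'n/a'})")

    if n_components == 1:
        i0, logd = best.x
        d = np.array([np.exp(logd)])
        fr = np.array([1.0])
    else:
        i0, logd1, logd2, logit_f = best.x
        f = 1.0 / (1.0 + np.exp(-logit_f))
        d = np.array([np.exp(logd1), np.exp(logd2)])
        fr = np.array([f, 1.0 - f])
        order = np.argsort(-d)
        d, fr = d[order], fr[order]
    residual = float(np.sqrt(2 * best.cost / y.size))
    # decay well sampled if the series spans at least one 1/e attenuation
    well = bool(np.max(k) * np.max(d) >= 1.0)
    return DiffusionFit(
        d=d,
        i0=float(i0),
        fractions=fr,
        residual=residual,
        n_components=n_components,
        well_conditioned=well,
    )


def fit_t2(decay: DecayCurve) -> RelaxationFit:
    """Monoexponential CPMG fit, I(t) = I0 exp(-t/T2)."""
    if decay.kind != "cpmg":
        raise ValueError("fit_t2 expects a cpmg decay")
    t, y = decay.abscissa, decay.intensity
    if np.ptp(y) == 0:
        raise FitError("constant intensities: T2 is unbounded")
    pos = y > 0
    if pos.sum() < 3:
        raise FitError("too few positive intensities for an exponential fit")
    rate_guess = max(np.polyfit(t[pos], np.log(y[pos]), 1)[0] * -1.0, 1e-12)

    def resid(p):
        i0, lograte = p
        return i0 * np.exp(-np.exp(lograte) * t) - y

    best = None
    for mult in (0.3, 1.0, 3.0):
        sol = optimize.least_squares(resid, [float(np.max(y)), np.log(rate_guess * mult)])
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success:
        raise FitError("relaxation fit did not converge")
    i0, lograte = best.x
    t2 = 1.0 / np.exp(lograte)
    return RelaxationFit(t2=float(t2), i0=float(i0), residual=float(np.sqrt(2 * best.cost / y.size)))


def hydrodynamic_radius(
    d_solute: float, d_reference: float, rh_reference: float = RH_DIOXANE_A
) -> float:
    """Stokes-Einstein radius by internal referencing: R_H = R_ref * D_ref / D.

    Both diffusion coefficients must come from the same run so units
    cancel; the result is in the units of ``rh_reference`` (Angstrom for
    the dioxane default, R_H = 2.12 A).
    """
    if d_solute <= 0 or d_reference <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return rh_reference * d_reference / d_solute


def round_rh(rh: float) -> float:
    """Interface rounding for radii: 2 decimals up to 20 A, 1 above."""
    return round(rh, 2) if rh <= 20 else round(rh, 1)


def stoichiometry_from_peaks(peaks: PeakTable) -> float:
    """Ligand:peptide molar ratio from proton-count-normalised peak areas.

    Each region's area divided by its protons-per-molecule estimates a
    quantity proportional to molecule count; the ratio of ligand to
    peptide estimates, averaged over all region pairs, is the
    stoichiometry.
    """
    rows = peaks.rows
    pep = rows[rows["species"] == "peptide"]
    lig = rows[rows["species"] == "ligand"]
    if pep.empty or lig.empty:
        raise ValueError("need at least one peptide and one ligand region")
    pep_norm = pep["area"].to_numpy() / pep["protons_per_molecule"].to_numpy()
    lig_norm = lig["area"].to_numpy() / lig["protons_per_molecule"].to_numpy()
    if np.any(pep_norm == 0):
        raise ValueError("zero peptide area: stoichiometry undefined")
    ratios = lig_norm[None, :] / pep_norm[:, None]
    return float(np.mean(ratios))


def calibrate_sehplc(standards: list[tuple[float, float]]) -> CalibrationModel:
    """Fit log10(R_H) vs elution volume on (R_H [A], volume [mL]) standards.

    Requires >= 3 standards; the validity range is the standards' volume
    span capped at 3.8 mL, beyond which column linearity is lost.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    rh = np.array([s[0] for s in standards], dtype=float)
    vol = np.array([s[1] for s in standards], dtype=float)
    if np.any(rh <= 0):
        raise ValueError("standard radii must be positive")
    res = stats.linregress(vol, np.log10(rh))
    upper = min(float(vol.max()), SEHPLC_LINEAR_LIMIT_ML)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        volume_range_ml=(float(vol.min()), upper),
    )


def sehplc_rh(model: CalibrationModel, volume_ml: float) -> tuple[float, bool]:
    """Predict R_H (A) at an elution volume; flags extrapolation.

    Returns ``(rh, in_range)``; ``in_range`` is False outside the
    calibration's validity range (in particular past 3.8 mL).
    """
    rh = 10.0 ** (model.intercept + model.slope * volume_ml)
    lo, hi = model.volume_range_ml
    return float(rh), bool(lo <= volume_ml <= hi)


def mean_residue_ellipticity(
    theta_mdeg: np.ndarray,
    conc_mg_ml: float,
    path_cm: float,
    mrw_g_mol: float,
) -> np.ndarray:
    """Mean residue ellipticity [theta] in deg cm^2/dmol.

    [theta] = theta_obs(mdeg) * MRW / (10 * l(cm) * c(mg/mL)); linear in
    the observed signal, inversely proportional to path length and
    concentration.
    """
    if conc_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    theta = np.asarray(theta_mdeg, dtype=float)
    return theta * mrw_g_mol / (10.0 * path_cm * conc_mg_ml)
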