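"""Equilibrium binding models and least-squares fitting.

Two model families:

* a depletion-corrected 1:1 isotherm for MST-style titrations, where the
  labeled protein concentration is comparable to the Kd so the free-ligand
  approximation does not hold, and
* a sequential (macroscopic) two-event binding polynomial for a DNA duplex
  carrying two protein sites, with an ITC injection-heat forward model and
  AICc-based selection between one and two binding events.

Units: concentrations µM, volumes µL, heats µcal, enthalpies kcal/mol.
The single conversion constant is ``UCAL_PER_UL_UM_KCAL``:
1 µL · 1 µM · 1 kcal/mol = 1e-12 mol·kcal/mol = 1e-3 µcal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "OneToOneFit",
    "SequentialBindingParams",
    "OneEventParams",
    "ITCExperiment",
    "ItcFit",
    "EventSelection",
    "CooperativityReport",
    "FitError",
    "fraction_bound_1to1",
    "predict_mst_signal",
    "fit_one_to_one",
    "solve_sequential_species",
    "predict_itc_heats",
    "predict_itc_heats_one_event",
    "fit_itc",
    "select_binding_events",
    "cooperativity_factor",
    "fold_change",
]

UCAL_PER_UL_UM_KCAL = 1e-3  # µL·µM·(kcal/mol) → µcal

_KD_START_GRID_UM = np.logspace(-2, 2, 8)  # documented multi-start grid
_LOG10_KD_BOUNDS = (-6.0, 6.0)


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is unidentifiable."""


@dataclass
class TitrationSeries:
    """One MST-style dose–response series at fixed labeled concentration."""

    labeled_total: float  # µM, the fluorescent species held constant
    titrant_total: np.ndarray  # µM, the titrated (DNA) concentrations
    signal: np.ndarray  # normalized fluorescence change, arbitrary units
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.labeled_total <= 0:
            raise ValueError("labeled_total must be > 0")
        if self.titrant_total.shape != self.signal.shape:
            raise ValueError("titrant_total and signal must have the same length")
        if np.any(self.titrant_total < 0):
            raise ValueError("titrant concentrations must be >= 0")


@dataclass(frozen=True)
class OneToOneFit:
    """Fitted 1:1 isotherm: Kd with signal baseline and amplitude."""

    kd: float  # µM
    baseline: float
    amplitude: float
    rss: float
    kd_ci95: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class SequentialBindingParams:
    """Macroscopic stepwise constants and enthalpies of two binding events."""

    kd1: float  # µM
    kd2: float  # µM
    dh1: float  # kcal/mol
    dh2: float  # kcal/mol

    def __post_init__(self):
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be > 0")


@dataclass(frozen=True)
class OneEventParams:
    kd: float  # µM
    dh: float  # kcal/mol


@dataclass
class ITCExperiment:
    """Injection geometry and measured (or simulated) heats."""

    cell_volume: float  # µL (V0)
    cell_DNA: float  # µM in the cell before injection (D0)
    syringe_protein: float  # µM in the syringe (Ps)
    injection_volumes: np.ndarray  # µL per injection
    heats: np.ndarray  # µcal per injection
    temperature: float = 20.0  # °C

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("all volumes must be > 0")
        if self.heats.shape != self.injection_volumes.shape:
            raise ValueError("one heat per injection required")
        if self.injection_volumes.sum() >= self.cell_volume:
            raise ValueError("total injected volume must stay below the cell volume")


@dataclass(frozen=True)
class ItcFit:
    model: str  # "one_event" or "two_event_sequential"
    params: SequentialBindingParams | OneEventParams
    dilution_offset: float  # µcal per µL injected
    rss: float
    aicc: float
    n_points: int


@dataclass(frozen=True)
class EventSelection:
    events: int  # 1 or 2 (protein per DNA)
    delta_aicc: float  # AICc(rejected) - AICc(selected), >= 0
    reliable: bool  # False when delta_aicc < 2
    fits: dict = field(repr=False, default_factory=dict)

    @property
    def stoichiometry(self) -> str:
        return f"{self.events}:1"


@dataclass(frozen=True)
class CooperativityReport:
    kd1: float
    kd2: float
    omega: float
    classification: str  # positive / none / negative


# --------------------------------------------------------------------------
# 1:1 depletion isotherm (MST)


def fraction_bound_1to1(Pt, Dt, Kd):
    """Fraction of the labeled species bound, with titrant depletion.

    Exact solution of P + D ⇌ PD mass balance:
    f = (Pt + Dt + Kd − sqrt((Pt+Dt+Kd)² − 4·Pt·Dt)) / (2·Pt).
    Vectorized over ``Dt``.
    """
    Pt = float(Pt)
    Dt = np.asarray(Dt, dtype=float)
    if Pt <= 0:
        raise ValueError("Pt must be > 0")
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    if np.any(Dt < 0):
        raise ValueError("Dt must be >= 0")
    s = Pt + Dt + Kd
    disc = np.maximum(s * s - 4.0 * Pt * Dt, 0.0)
    f = (s - np.sqrt(disc)) / (2.0 * Pt)
    return np.clip(f, 0.0, 1.0) if f.ndim else float(np.clip(f, 0.0, 1.0))


def predict_mst_signal(labeled_total, titrant_total, kd, baseline=0.0, amplitude=1.0):
    """Affine map of the bound fraction onto the measured signal."""
    f = fraction_bound_1to1(labeled_total, titrant_total, kd)
    return baseline + amplitude * np.asarray(f)


def fit_one_to_one(series: TitrationSeries | list[TitrationSeries]) -> OneToOneFit:
    """Least-squares fit of (Kd, baseline, amplitude) to titration data.

    Replicate series are pooled. Kd is optimized on a log10 scale with a
    fixed 8-point multi-start grid over 0.01–100 µM, so the fit is
    deterministic given the data. The 95% interval on Kd comes from the
    Gauss–Newton covariance approximation on log10(Kd).
    """
    if isinstance(series, TitrationSeries):
        series = [series]
    if not series:
        raise ValueError("no titration data")
    pt = series[0].labeled_total
    if any(s.labeled_total != pt for s in series):
        raise ValueError("all replicates must share the same labeled_total")
    dt = np.concatenate([s.titrant_total for s in series])
    y = np.concatenate([s.signal for s in series])
    if len(np.unique(dt[dt > 0])) < 6:
        warnings.warn("fewer than 6 distinct titrant concentrations; Kd may be poorly constrained")

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1e-12)

    def resid(theta):
        logkd, base, amp = theta
        return predict_mst_signal(pt, dt, 10.0**logkd, base, amp) - y

    best = None
    for kd0 in _KD_START_GRID_UM:
        x0 = np.array([np.log10(kd0), y.min(), span if span > 0 else 1.0])
        try:
            sol = optimize.least_squares(
                resid,
                x0,
                bounds=([_LOG10_KD_BOUNDS[0], -np.inf, -np.inf], [_LOG10_KD_BOUNDS[1], np.inf, np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("1:1 isotherm fit did not converge from any start")
    logkd, base, amp = best.x
    if abs(amp) < 1e-4 * scale:
        raise FitError("signal amplitude is indistinguishable from zero; Kd unidentifiable")
    if logkd <= _LOG10_KD_BOUNDS[0] + 1e-6 or logkd >= _LOG10_KD_BOUNDS[1] - 1e-6:
        raise FitError("Kd ran to the bound of the search range; unidentifiable data")
    rss = float(2 * best.cost)
    n, p = len(y), 3
    # Gauss-Newton covariance on theta
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / max(n - p, 1)
        se_logkd = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_logkd = np.inf
    kd = 10.0**logkd
    ci = (kd * 10.0 ** (-1.96 * se_logkd), kd * 10.0 ** (1.96 * se_logkd))
    return OneToOneFit(kd, float(base), float(amp), rss, ci, n)


# --------------------------------------------------------------------------
# Sequential two-event binding polynomial and ITC forward model


def solve_sequential_species(Pt: float, Dt: float, kd1: float, kd2: float) -> dict:
    """Equilibrium species of D + P ⇌ DP, DP + P ⇌ DP2 (macroscopic Kds).

    With Z(p) = 1 + p/Kd1 + p²/(Kd1·Kd2), the DNA states are D = Dt/Z,
    DP = Dt·(p/Kd1)/Z, DP2 = Dt·p²/(Kd1·Kd2)/Z and free protein p solves
    Pt = p + DP + 2·DP2, which is strictly increasing in p so the root in
    [0, Pt] is unique (bracketed bisection/Brent to 1e-12 relative).
    """
    if Pt < 0 or Dt < 0 or kd1 <= 0 or kd2 <= 0:
        raise ValueError("concentrations must be >= 0 and Kds > 0")

    def species(p):
        z = 1.0 + p / kd1 + p * p / (kd1 * kd2)
        d = Dt / z
        dp = Dt * (p / kd1) / z
        dp2 = Dt * (p * p / (kd1 * kd2)) / z
        return d, dp, dp2

    if Pt == 0.0:
        return {"free_P": 0.0, "D": Dt, "DP": 0.0, "DP2": 0.0}

    def f(p):
        _, dp, dp2 = species(p)
        return p + dp + 2.0 * dp2 - Pt

    p = optimize.brentq(f, 0.0, Pt, rtol=1e-14, xtol=1e-300, maxiter=200)
    d, dp, dp2 = species(p)
    return {"free_P": p, "D": d, "DP": dp, "DP2": dp2}


def _itc_concentrations(cell_volume, cell_DNA, syringe_protein, injection_volumes):
    """Cell concentrations after each injection under perfusion displacement.

    The displaced volume leaves the active cell; standard instrument
    correction: after cumulative injected volume V, the remaining fractions
    are Dt = D0·(1−V/2V0)/(1+V/2V0) and Pt = Ps·(V/V0)/(1+V/2V0).
    """
    v = np.cumsum(np.asarray(injection_volumes, dtype=float))
    r = v / (2.0 * cell_volume)
    dt = cell_DNA * (1.0 - r) / (1.0 + r)
    pt = syringe_protein * (v / cell_volume) / (1.0 + r)
    return dt, pt


def _heats_from_Q(Q, injection_volumes, cell_volume, dilution_offset):
    """Measured per-injection heats from total heat content Q_i (Q_0 = 0)."""
    v = np.asarray(injection_volumes, dtype=float)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    return Q - Qprev + (v / cell_volume) * (Q + Qprev) / 2.0 + dilution_offset * v


def predict_itc_heats(
    exp: ITCExperiment,
    params: SequentialBindingParams,
    dilution_offset: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (µcal) for the two-event sequential model.

    Total heat content after injection i is
    Q_i = V0·(ΔH1·[DP]_i + (ΔH1+ΔH2)·[DP2]_i) (in µcal via the unit
    constant); the measured heat corrects for the displaced volume and adds
    a constant per-µL dilution offset.
    """
    dt, pt = _itc_concentrations(
        exp.cell_volume, exp.cell_DNA, exp.syringe_protein, exp.injection_volumes
    )
    Q = np.empty_like(dt)
    for i, (d, p) in enumerate(zip(dt, pt)):
        sp = solve_sequential_species(p, d, params.kd1, params.kd2)
        Q[i] = (
            UCAL_PER_UL_UM_KCAL
            * exp.cell_volume
            * (params.dh1 * sp["DP"] + (params.dh1 + params.dh2) * sp["DP2"])
        )
    return _heats_from_Q(Q, exp.injection_volumes, exp.cell_volume, dilution_offset)


def predict_itc_heats_one_event(
    exp: ITCExperiment,
    params: OneEventParams,
    dilution_offset: float = 0.0,
) -> np.ndarray:
    """Per-injection heats for a single 1:1 binding event."""
    dt, pt = _itc_concentrations(
        exp.cell_volume, exp.cell_DNA, exp.syringe_protein, exp.injection_volumes
    )
    s = pt + dt + params.kd
    dp = (s - np.sqrt(np.maximum(s * s - 4.0 * pt * dt, 0.0))) / 2.0
    Q = UCAL_PER_UL_UM_KCAL * exp.cell_volume * params.dh * dp
    return _heats_from_Q(Q, exp.injection_volumes, exp.cell_volume, dilution_offset)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_itc(
    exp: ITCExperiment | Sequence[ITCExperiment],
    model: str = "two_event_sequential",
) -> ItcFit:
    """Least-squares fit of an ITC binding model to injection heats.

    Replicate experiments may be passed as a sequence and are fit globally
    with shared parameters. Kds are optimized as log10 with a fixed
    multi-start grid; enthalpies are started from the total integrated heat
    assuming saturation of the cell DNA. A constant per-volume dilution
    offset is co-fitted (shared across replicates).
    """
    exps = [exp] if isinstance(exp, ITCExperiment) else list(exp)
    if not exps:
        raise ValueError("no ITC data")
    y = np.concatenate([e.heats for e in exps])
    n = len(y)
    if any(len(e.heats) < 8 for e in exps):
        raise ValueError("need at least 8 injections per experiment")
    e0 = exps[0]
    dh_total0 = float(e0.heats.sum()) / (UCAL_PER_UL_UM_KCAL * e0.cell_volume * e0.cell_DNA)

    if model == "one_event":
        def resid(theta):
            logkd, dh, off = theta
            p = OneEventParams(10.0**logkd, dh)
            return np.concatenate([predict_itc_heats_one_event(e, p, off) for e in exps]) - y

        starts = [np.array([np.log10(k), dh_total0 if dh_total0 != 0 else -5.0, 0.0])
                  for k in (0.03, 0.3, 3.0, 30.0)]
        nparams = 3
    elif model == "two_event_sequential":
        def resid(theta):
            logk1, logk2, dh1, dh2, off = theta
            p = SequentialBindingParams(10.0**logk1, 10.0**logk2, dh1, dh2)
            return np.concatenate([predict_itc_heats(e, p, off) for e in exps]) - y

        grid = (0.03, 0.3, 3.0, 30.0)
        dh0 = dh_total0 / 2.0 if dh_total0 != 0 else -5.0
        starts = [np.array([np.log10(a), np.log10(b), dh0, dh0, 0.0]) for a in grid for b in grid]
        nparams = 5
    else:
        raise ValueError(f"unknown model {model!r}")

    lo = np.full(nparams, -np.inf)
    hi = np.full(nparams, np.inf)
    n_kd = 1 if model == "one_event" else 2
    for i in range(n_kd):
        lo[i], hi[i] = _LOG10_KD_BOUNDS

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(f"ITC {model} fit did not converge from any start")
    rss = float(2 * best.cost)
    if model == "one_event":
        params = OneEventParams(10.0 ** best.x[0], float(best.x[1]))
        off = float(best.x[2])
    else:
        params = SequentialBindingParams(
            10.0 ** best.x[0], 10.0 ** best.x[1], float(best.x[2]), float(best.x[3])
        )
        off = float(best.x[4])
    return ItcFit(model, params, off, rss, _aicc(rss, n, nparams), n)


def _null_model_aicc(exps: Sequence[ITCExperiment]) -> float:
    """AICc of a no-binding model: heats are dilution offset times volume."""
    v = np.concatenate([e.injection_volumes for e in exps])
    q = np.concatenate([e.heats for e in exps])
    off = float(np.dot(q, v) / np.dot(v, v))
    rss = float(np.sum((q - off * v) ** 2))
    return _aicc(rss, len(q), 1)


def select_binding_events(exp: ITCExperiment | Sequence[ITCExperiment]) -> EventSelection:
    """Choose between one and two binding events by small-sample AICc.

    Returns the event count of the lower-AICc model (stoichiometry
    events:1, protein:DNA). The selection is flagged unreliable when the
    two binding models are separated by ΔAICc < 2, or when neither beats a
    no-binding (dilution-only) null model by at least 2 — pure-noise heats
    cannot support a stoichiometry claim.
    """
    exps = [exp] if isinstance(exp, ITCExperiment) else list(exp)
    fits = {}
    errors = []
    for model, k in (("one_event", 1), ("two_event_sequential", 2)):
        try:
            fits[k] = fit_itc(exps, model)
        except (FitError, ValueError) as e:  # pragma: no cover - defensive
            errors.append(e)
    if not fits:
        raise FitError(f"both ITC fits failed: {errors}")
    if len(fits) == 1:
        (k, fit), = fits.items()
        return EventSelection(k, np.inf, True, {k: fit})
    delta = abs(fits[1].aicc - fits[2].aicc)
    events = 1 if fits[1].aicc <= fits[2].aicc else 2
    has_signal = _null_model_aicc(exps) - fits[events].aicc >= 2.0
    return EventSelection(events, float(delta), bool(delta >= 2.0 and has_signal), fits)


# --------------------------------------------------------------------------
# Derived binding quantities


def cooperativity_factor(kd1: float, kd2: float) -> CooperativityReport:
    """Interaction factor ω = 4·Kd1/Kd2 between two binding events.

    Two identical independent sites give macroscopic Kd1/Kd2 = 1/4 from
    statistical factors alone, so ω = 1 means no cooperativity; ω > 1 means
    the second event is tighter than independence predicts (positive
    cooperativity).
    """
    if kd1 <= 0 or kd2 <= 0:
        raise ValueError("dissociation constants must be > 0")
    omega = 4.0 * kd1 / kd2
    rtol = 1e-6
    if omega > 1.0 + rtol:
        cls = "positive"
    elif omega < 1.0 - rtol:
        cls = "negative"
    else:
        cls = "none"
    return CooperativityReport(kd1, kd2, omega, cls)


def fold_change(kd_a: float, kd_b: float) -> float:
    """Plain affinity ratio Kd_a / Kd_b (>1 means b binds tighter)."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_a / kd_b
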