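"""Equilibrium and kinetic ligand-binding models for LDL-receptor studies.

Two model families:

* **One-site saturation binding** — specific binding of labelled LDL to a
  cell surface, ``B(L) = B_max * L / (K_d + L)`` (optionally plus a linear
  nonspecific term ``NS * L``); concentrations in µg ml⁻¹, bound ligand in
  ng per mg cell protein.

* **1:1 SPR kinetics** — biosensor response to analyte injections,
  ``dR/dt = k_a * C(t) * (R_max - R) - k_d * R`` with piecewise-constant
  analyte concentration ``C(t)`` set by the injection schedule (zero during
  dissociation).  Single-cycle mode injects increasing concentrations
  back-to-back with no regeneration, carrying the response over between
  injections.  The apparent affinity is ``K_d = k_d / k_a``.

Because ``C(t)`` is piecewise constant, the ODE has an exact closed-form
solution on each phase: with rate ``k_obs = k_a*C + k_d`` and steady state
``R_eq = k_a*C*R_max / k_obs``, ``R(t) = R_eq + (R0 - R_eq)*exp(-k_obs*(t -
t0))``.  Simulation and fitting both use this exact propagator.

Units are kept symbolic: fitted ``K_d`` comes out in whatever concentration
unit the schedule or data use (nM, µM, µg ml⁻¹ …) and is never converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import FitError


@dataclass
class Injection:
    concentration: float  # analyte concentration (units of the experiment)
    start: float  # s
    stop: float  # s


@dataclass
class InjectionSchedule:
    """Ordered injections followed by a final dissociation phase."""

    injections: list[Injection]
    dissociation_end: float
    single_cycle: bool = True

    def __post_init__(self) -> None:
        prev_stop, prev_conc = -np.inf, -np.inf
        for inj in self.injections:
            if inj.start < prev_stop or inj.stop <= inj.start:
                raise ValueError("injections must be non-overlapping with stop > start")
            if self.single_cycle and inj.concentration <= prev_conc:
                raise ValueError("single-cycle injections must increase in concentration")
            prev_stop, prev_conc = inj.stop, inj.concentration
        if self.injections and self.dissociation_end < self.injections[-1].stop:
            raise ValueError("dissociation_end precedes last injection stop")

    def concentration_at(self, t: float) -> float:
        for inj in self.injections:
            if inj.start <= t < inj.stop:
                return inj.concentration
        return 0.0

    def phase_boundaries(self) -> np.ndarray:
        pts = {0.0, self.dissociation_end}
        for inj in self.injections:
            pts.update((inj.start, inj.stop))
        return np.array(sorted(pts))


@dataclass
class Sensorgram:
    time: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    schedule: InjectionSchedule | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BindingFit:
    """Fitted binding parameters with asymptotic standard errors."""

    k_d: float  # equilibrium dissociation constant, input concentration units
    b_max: float | None = None  # ng mg^-1 (saturation fits)
    r_max: float | None = None  # RU (kinetic fits)
    k_a: float | None = None  # (conc unit)^-1 s^-1
    k_d_rate: float | None = None  # s^-1
    nonspecific: float | None = None
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")


def saturation_model(conc: np.ndarray, b_max: float, k_d: float, ns: float = 0.0):
    """One-site specific binding isotherm, optional linear nonspecific term."""
    conc = np.asarray(conc, dtype=float)
    return b_max * conc / (k_d + conc) + ns * conc


def fit_saturation(
    concentrations,
    bound,
    nonspecific: bool = False,
    weights=None,
) -> BindingFit:
    """Least-squares fit of the one-site isotherm ``B_max*L/(K_d+L)``.

    ``weights`` (optional) are per-point standard deviations passed straight
    to the χ² (use sqrt(counts) for count-derived radioligand data).  Raises
    :class:`FitError` on non-convergence or a K_d pinned to a bound.
    """
    conc = np.asarray(concentrations, dtype=float)
    b = np.asarray(bound, dtype=float)
    if conc.size < 4 or np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be >= 0 and strictly increasing")
    b_max0 = float(b.max()) * 1.2 + 1e-12
    k_d0 = float(np.median(conc)) or 1.0
    if nonspecific:
        p0, bounds = [b_max0, k_d0, 0.0], ([0, 1e-12, 0], [np.inf, np.inf, np.inf])
        model = saturation_model
    else:
        p0, bounds = [b_max0, k_d0], ([0, 1e-12], [np.inf, np.inf])
        model = lambda L, bm, kd: saturation_model(L, bm, kd, 0.0)  # noqa: E731
    try:
        popt, pcov = curve_fit(
            model, conc, b, p0=p0, bounds=bounds, sigma=weights, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"saturation fit failed to converge: {exc}") from exc
    if popt[1] <= 2e-12 or popt[1] >= conc.max() * 1e4:
        raise FitError(f"K_d at parameter bound ({popt[1]:.3g}); data do not constrain it")
    perr = np.sqrt(np.diag(pcov))
    resid = b - model(conc, *popt)
    fit = BindingFit(
        k_d=float(popt[1]),
        b_max=float(popt[0]),
        nonspecific=float(popt[2]) if nonspecific else None,
        stderr={"b_max": float(perr[0]), "k_d": float(perr[1])},
        residual_norm=float(np.linalg.norm(resid)),
    )
    if nonspecific:
        fit.stderr["nonspecific"] = float(perr[2])
    return fit


def _propagate(
    t: np.ndarray, schedule: InjectionSchedule, k_a: float, k_d: float, r_max: float
) -> np.ndarray:
    """Exact piecewise solution of the 1:1 model at sample times ``t``."""
    bounds = schedule.phase_boundaries()
    r = np.empty_like(t, dtype=float)
    r0, t0 = 0.0, float(bounds[0])
    for i in range(len(bounds)):
        t_start = float(bounds[i])
        t_end = float(bounds[i + 1]) if i + 1 < len(bounds) else np.inf
        c = schedule.concentration_at(t_start)
        k_obs = k_a * c + k_d
        r_eq = (k_a * c * r_max / k_obs) if k_obs > 0 else 0.0
        sel = (t >= t_start) & (t < t_end) if np.isfinite(t_end) else (t >= t_start)
        if np.any(sel):
            r[sel] = r_eq + (r0 - r_eq) * np.exp(-k_obs * (t[sel] - t_start))
        if np.isfinite(t_end):
            r0 = r_eq + (r0 - r_eq) * np.exp(-k_obs * (t_end - t_start))
    r[t < bounds[0]] = 0.0
    return r


def simulate_sensorgram(
    k_a: float,
    k_d_rate: float,
    r_max: float,
    schedule: InjectionSchedule,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sensorgram:
    """Forward-simulate a sensorgram under the 1:1 model.

    Integrates ``dR/dt = k_a*C(t)*(R_max - R) - k_d*R`` exactly (closed form
    per constant-concentration phase, response carried over between
    single-cycle injections); optionally adds white Gaussian noise (RU) and a
    linear baseline drift (RU/s).
    """
    if k_a <= 0 or k_d_rate <= 0 or r_max <= 0:
        raise ValueError("k_a, k_d_rate and R_max must be > 0")
    t = np.arange(0.0, schedule.dissociation_end + dt / 2, dt)
    r = _propagate(t, schedule, k_a, k_d_rate, r_max)
    if drift:
        r = r + drift * t
    if noise_sd:
        rng = rng if rng is not None else np.random.default_rng()
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, schedule=schedule)


def fit_1to1_kinetics(sensorgram: Sensorgram) -> BindingFit:
    """Global fit of (k_a, k_d, R_max) to a (double-referenced) sensorgram.

    All injection and dissociation phases are fit jointly with the same
    exact piecewise propagator used for simulation; optimisation is over
    log-rates for scale invariance.  Raises :class:`FitError` for flat
    (non-identifiable) sensorgrams or non-convergence.
    """
    if sensorgram.schedule is None:
        raise ValueError("sensorgram must carry its injection schedule")
    t, r = sensorgram.time, sensorgram.response
    span = float(r.max() - r.min())
    if span <= 0 or float(np.abs(r).max()) < 1e-9:
        raise FitError("flat sensorgram; kinetic parameters not identifiable")
    sched = sensorgram.schedule
    c_mid = float(np.median([inj.concentration for inj in sched.injections]))

    def resid(p):
        log_ka, log_kd, r_max = p
        return _propagate(t, sched, np.exp(log_ka), np.exp(log_kd), r_max) - r

    # moderate-affinity initial guess: K_d near the mid concentration
    p0 = [np.log(0.01 / c_mid), np.log(0.01), span * 1.5]
    sol = least_squares(resid, p0, method="lm", max_nfev=20000)
    if not sol.success:
        raise FitError(f"kinetic fit did not converge: {sol.message}")
    k_a, k_d_rate, r_max = np.exp(sol.x[0]), np.exp(sol.x[1]), sol.x[2]
    # asymptotic covariance from the Jacobian at the optimum
    stderr: dict[str, float] = {}
    try:
        dof = max(t.size - 3, 1)
        s2 = 2 * sol.cost / dof
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.diag(cov))
        stderr = {
            "k_a": float(se[0] * k_a),  # delta method from log-scale
            "k_d_rate": float(se[1] * k_d_rate),
            "r_max": float(se[2]),
        }
    except np.linalg.LinAlgError:
        pass
    return BindingFit(
        k_d=float(k_d_rate / k_a),
        r_max=float(r_max),
        k_a=float(k_a),
        k_d_rate=float(k_d_rate),
        stderr=stderr,
        residual_norm=float(np.sqrt(2 * sol.cost)),
    )


def double_reference(
    raw: Sensorgram, reference_surface: Sensorgram, buffer_blank: Sensorgram
) -> Sensorgram:
    """Double referencing: subtract the reference-surface trace and the
    buffer-blank trace from the raw response (all on one time base)."""
    for other in (reference_surface, buffer_blank):
        if other.time.shape != raw.time.shape or not np.allclose(other.time, raw.time):
            raise ValueError("all traces must share the same time base")
    corrected = raw.response - reference_surface.response - buffer_blank.response
    if np.allclose(corrected, -raw.response) and np.any(raw.response != 0):
        import logging

        logging.getLogger(__name__).warning(
            "double referencing returned the negated raw trace; "
            "reference and blank likely duplicate the raw signal"
        )
    return Sensorgram(time=raw.time.copy(), response=corrected, schedule=raw.schedule)


def competition_analysis(
    naive_fit: BindingFit, presaturated_fit: BindingFit, tolerance: float = 2.0
) -> dict:
    """Compare analyte binding on a naive vs pre-saturated surface.

    Reports the K_d ratio and amplitude (R_max or B_max) ratio
    (presaturated / naive); the verdict is ``"non-competitive"`` when both
    ratios lie within ``[1/tolerance, tolerance]`` — i.e. pre-occupying the
    surface with the other ligand changed neither affinity nor capacity —
    and ``"competitive"`` otherwise.
    """
    amp_naive = naive_fit.r_max if naive_fit.r_max is not None else naive_fit.b_max
    amp_pre = (
        presaturated_fit.r_max if presaturated_fit.r_max is not None else presaturated_fit.b_max
    )
    kd_ratio = presaturated_fit.k_d / naive_fit.k_d
    amp_ratio = (amp_pre / amp_naive) if amp_naive else np.inf
    non_comp = (1 / tolerance <= kd_ratio <= tolerance) and (
        1 / tolerance <= amp_ratio <= tolerance
    )
    return {
        "kd_ratio": float(kd_ratio),
        "amplitude_ratio": float(amp_ratio),
        "verdict": "non-competitive" if non_comp else "competitive",
    }


def stability_point_quantitation(
    sensorgrams: dict[str, Sensorgram],
    normalizer: str,
    offset_s: float = 5.0,
) -> dict[str, float]:
    """Quantify binding at the stability reference point.

    Reads each trace's response at ``offset_s`` seconds after its last
    injection stops (initial phase of dissociation, free of bulk
    refractive-index jumps) and normalises by the ``normalizer`` trace's
    amplitude at the same point.
    """
    if normalizer not in sensorgrams:
        raise KeyError(f"normalizer {normalizer!r} not among traces")

    def read(sg: Sensorgram) -> float:
        if sg.schedule is None or not sg.schedule.injections:
            raise ValueError("trace needs a schedule to locate the dissociation start")
        t_ref = sg.schedule.injections[-1].stop + offset_s
        if t_ref > sg.time[-1]:
            raise ValueError(f"stability point {t_ref:.1f}s beyond trace end {sg.time[-1]:.1f}s")
        return float(np.interp(t_ref, sg.time, sg.response))

    ref_amp = read(sensorgrams[normalizer])
    if ref_amp == 0.0:
        raise ValueError("normalizer amplitude is zero at the stability point")
    return {name: read(sg) / ref_amp for name, sg in sensorgrams.items()}
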