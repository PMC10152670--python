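"""1:1 binding kinetics for Bio-Layer Interferometry sensorgrams.

BLI reports an optical wavelength shift proportional to the mass bound on
the biosensor tip.  Under the 1:1 (Langmuir) model with analyte
concentration C held constant:

    association:  R(t) = R_eq * (1 - exp(-(k_on*C + k_off) * t)),
                  R_eq = R_max * C / (C + K_D)
    dissociation: R(t) = R0 * exp(-k_off * t)

with K_D = k_off / k_on.  This module simulates phase-structured
sensorgrams, fits the kinetic model globally across concentrations, and
fits the steady-state hyperbola R_eq(C) for an equilibrium K_D.

Units: concentrations and K_D in molar (M) at the function level; the
reporting dataclasses also expose K_D in nM, the unit affinities in this
range are usually quoted in.  k_on is in 1/(M s), k_off in 1/s, responses
in nm wavelength shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PhaseSchedule",
    "Sensorgram",
    "KineticFit",
    "SteadyStateFit",
    "model_response",
    "simulate_sensorgram",
    "fit_kinetic_global",
    "extract_req",
    "fit_steady_state",
]

PHASE_NAMES = ("baseline1", "loading", "baseline2", "association",
               "dissociation")


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations (s) of the five standard BLI phases plus sampling interval.

    The default schedule is baseline 120 s, loading 300 s, baseline 120 s,
    association 300 s, dissociation 900 s.
    """

    durations: tuple[float, ...] = (120.0, 300.0, 120.0, 300.0, 900.0)
    interval: float = 1.0

    def __post_init__(self) -> None:
        if len(self.durations) != len(PHASE_NAMES):
            raise ValueError(f"expected {len(PHASE_NAMES)} phase durations")
        if any(d <= 0 for d in self.durations):
            raise ValueError("phase durations must be positive")
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")

    def times(self, phase: str) -> np.ndarray:
        """Phase-relative sample times, starting at one interval."""
        dur = self.durations[PHASE_NAMES.index(phase)]
        n = int(np.floor(dur / self.interval))
        return np.arange(1, n + 1) * self.interval


@dataclass
class Sensorgram:
    """One response-versus-time trace at a single analyte concentration."""

    concentration_nM: float
    time_s: np.ndarray       # phase-relative times
    response_nm: np.ndarray
    phase: np.ndarray        # phase label per sample

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_nm = np.asarray(self.response_nm, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (len(self.time_s) == len(self.response_nm) == len(self.phase)):
            raise ValueError("time, response and phase must align")
        if not np.all(np.isfinite(self.response_nm)):
            raise ValueError("responses must be finite")
        for name in np.unique(self.phase):
            t = self.time_s[self.phase == name]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing in {name}")

    def segment(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.phase == phase
        return self.time_s[mask], self.response_nm[mask]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "time_s": self.time_s, "response_nm": self.response_nm,
            "phase": self.phase,
            "concentration_nM": self.concentration_nM})

    @classmethod
    def from_frame(cls, frame) -> "Sensorgram":
        conc = frame["concentration_nM"].iloc[0]
        return cls(float(conc), frame["time_s"].to_numpy(),
                   frame["response_nm"].to_numpy(),
                   frame["phase"].to_numpy())


def model_response(
    t: np.ndarray | float,
    C: float,
    k_on: float,
    k_off: float,
    R_max: float,
    phase: str = "association",
    R0: float = 0.0,
) -> np.ndarray | float:
    """1:1 model response at phase-relative time(s) ``t``.

    ``C`` in molar.  Association rises to R_eq = R_max*C/(C+K_D) with
    observed rate k_obs = k_on*C + k_off; dissociation decays from ``R0``
    at rate k_off; baseline and loading phases are constant at ``R0``
    (the immobilization offset is assumed removed by reference
    subtraction).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if C < 0:
        raise ValueError("concentration must be non-negative")
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    if phase == "association":
        kd = k_off / k_on
        req = R_max * C / (C + kd) if C > 0 else 0.0
        kobs = k_on * C + k_off
        out = req * (1.0 - np.exp(-kobs * t))
    elif phase == "dissociation":
        out = R0 * np.exp(-k_off * t)
    elif phase in ("baseline1", "baseline2", "loading"):
        out = np.full_like(t, R0, dtype=float)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out if out.ndim else float(out)


def simulate_sensorgram(
    C: float,
    k_on: float,
    k_off: float,
    R_max: float,
    schedule: PhaseSchedule | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sensorgram:
    """Noiseless or Gaussian-noised 1:1 sensorgram over a full schedule."""
    schedule = schedule or PhaseSchedule()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = rng or np.random.default_rng(0)
    times, responses, phases = [], [], []
    R_assoc_end = 0.0
    for name in PHASE_NAMES:
        t = schedule.times(name)
        if name == "association":
            r = model_response(t, C, k_on, k_off, R_max, "association")
            R_assoc_end = float(np.asarray(r)[-1])
        elif name == "dissociation":
            r = model_response(t, C, k_on, k_off, R_max, "dissociation",
                               R0=R_assoc_end)
        else:
            r = np.zeros_like(t)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=t.shape)
        times.append(t)
        responses.append(np.asarray(r, dtype=float))
        phases.append(np.full(t.shape, name, dtype=object))
    return Sensorgram(C * 1e9, np.concatenate(times),
                      np.concatenate(responses), np.concatenate(phases))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class KineticFit:
    """Globally fitted 1:1 kinetic parameters.

    K_D is derived from the fitted rates (K_D = k_off / k_on exactly).
    Standard errors come from the Gauss-Newton approximation of the
    parameter covariance at the optimum.
    """

    k_on: float
    k_off: float
    R_max: float
    rss: float
    converged: bool
    stderr: dict = field(default_factory=dict)
    message: str = ""

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant in molar."""
        return self.k_off / self.k_on

    @property
    def K_D_nM(self) -> float:
        return self.K_D * 1e9


@dataclass
class SteadyStateFit:
    """Hyperbolic fit of equilibrium response versus concentration."""

    K_D: float     # molar
    R_max: float
    rss: float
    converged: bool
    flags: list = field(default_factory=list)

    @property
    def K_D_nM(self) -> float:
        return self.K_D * 1e9


def _exp_rise(t, plateau, kobs):
    return plateau * (1.0 - np.exp(-kobs * t))


def _initial_kinetic_guess(sensorgrams) -> tuple[float, float, float]:
    """Heuristic (k_on, k_off, R_max) start: k_off from log-linear early
    dissociation, per-curve k_obs from single-exponential association fits,
    k_on from the slope of k_obs against concentration."""
    koffs, kobs_list, concs, rmax_guess = [], [], [], 0.0
    for sg in sensorgrams:
        C = sg.concentration_nM * 1e-9
        td, rd = sg.segment("dissociation")
        early = slice(0, max(5, len(td) // 5))
        r_early = rd[early]
        pos = r_early > max(1e-9, 0.01 * np.abs(rd).max())
        if pos.sum() >= 3:
            slope, intercept, *_ = stats.linregress(
                td[early][pos], np.log(r_early[pos]))
            if slope < 0:
                koffs.append(-slope)
        ta, ra = sg.segment("association")
        plateau0 = max(ra[-max(1, len(ra) // 20):].mean(), 1e-6)
        try:
            popt, _ = optimize.curve_fit(
                _exp_rise, ta, ra, p0=[plateau0, 1.0 / ta[-1]],
                maxfev=2000)
            if popt[1] > 0:
                kobs_list.append(popt[1])
                concs.append(C)
        except RuntimeError:
            pass
        rmax_guess = max(rmax_guess, plateau0)
    k_off0 = float(np.median(koffs)) if koffs else 1e-2
    k_on0 = 1e5
    if len(kobs_list) >= 2:
        slope, intercept, *_ = stats.linregress(concs, kobs_list)
        if slope > 0:
            k_on0 = slope
        if intercept > 0 and not koffs:
            k_off0 = intercept
    return k_on0, k_off0, max(rmax_guess * 1.1, 1e-3)


def fit_kinetic_global(sensorgrams: list[Sensorgram]) -> KineticFit:
    """Fit k_on, k_off and R_max shared across all concentrations.

    Requires at least two distinct concentrations (a single curve cannot
    separate k_on from k_off and R_max).  Non-convergence is reported via
    the ``converged`` flag, never silently.
    """
    concs = sorted({sg.concentration_nM for sg in sensorgrams})
    if len(concs) < 2:
        raise ValueError(
            "global kinetic fit needs >= 2 distinct concentrations")
    for sg in sensorgrams:
        for phase in ("association", "dissociation"):
            if sg.segment(phase)[0].size == 0:
                raise ValueError(f"sensorgram missing {phase} segment")

    k_on0, k_off0, rmax0 = _initial_kinetic_guess(sensorgrams)
    x0 = np.log([k_on0, k_off0, rmax0])

    def residuals(x):
        k_on, k_off, r_max = np.exp(x)
        res = []
        for sg in sensorgrams:
            C = sg.concentration_nM * 1e-9
            ta, ra = sg.segment("association")
            model_a = model_response(ta, C, k_on, k_off, r_max, "association")
            r0 = model_response(ta[-1], C, k_on, k_off, r_max, "association")
            td, rd = sg.segment("dissociation")
            model_d = model_response(td, C, k_on, k_off, r_max,
                                     "dissociation", R0=r0)
            res.append(model_a - ra)
            res.append(model_d - rd)
        return np.concatenate(res)

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14, max_nfev=20000)
    k_on, k_off, r_max = np.exp(sol.x)
    rss = float(2.0 * sol.cost)
    stderr = {}
    try:
        n_pts = sol.fun.size
        dof = max(n_pts - sol.x.size, 1)
        s2 = rss / dof
        jtj = sol.jac.T @ sol.jac
        cov_log = s2 * np.linalg.inv(jtj)
        # delta method back from log scale
        se_log = np.sqrt(np.diag(cov_log))
        for name, val, se in zip(("k_on", "k_off", "R_max"),
                                 (k_on, k_off, r_max), se_log):
            stderr[name] = val * se
    except np.linalg.LinAlgError:
        pass
    return KineticFit(float(k_on), float(k_off), float(r_max), rss,
                      converged=bool(sol.success), stderr=stderr,
                      message=sol.message)


def extract_req(sensorgram: Sensorgram, method: str = "tail_mean",
                tail_fraction: float = 0.05) -> float:
    """Estimate the equilibrium response of one association phase.

    ``tail_mean`` (default) averages the final ``tail_fraction`` of the
    association samples; ``exponential`` fits a single-exponential rise
    and returns its plateau (preferred for slow-binding curves that do not
    equilibrate within the phase).  Associations shorter than 20 samples
    fall back to the exponential plateau with a warning.
    """
    t, r = sensorgram.segment("association")
    if t.size == 0:
        raise ValueError("sensorgram has no association segment")
    if method == "tail_mean" and t.size < 20:
        warnings.warn("association segment < 20 samples; "
                      "falling back to exponential-plateau estimate",
                      stacklevel=2)
        method = "exponential"
    if method == "tail_mean":
        n_tail = max(1, int(round(tail_fraction * t.size)))
        return float(r[-n_tail:].mean())
    if method == "exponential":
        if np.allclose(r, 0.0):
            return 0.0
        p0 = [max(r[-1], 1e-6), 1.0 / t[-1]]
        popt, _ = optimize.curve_fit(_exp_rise, t, r, p0=p0, maxfev=5000)
        return float(popt[0])
    raise ValueError(f"unknown method {method!r}")


def fit_steady_state(
    req_by_concentration: list[tuple[float, float]],
) -> SteadyStateFit:
    """Fit R_eq = R_max * C / (C + K_D) to (concentration, R_eq) pairs.

    Concentrations in molar.  Positivity of both parameters is enforced by
    optimizing in log space; initialization is R_max = 1.1 * max(R_eq),
    K_D = median(C).  Identifiability limits are flagged rather than
    hidden: K_D far above the largest tested concentration (linear
    regime) yields ``lower_bound_only``; K_D far below the smallest
    (saturation) yields ``saturated``.
    """
    pairs = [(float(c), float(r)) for c, r in req_by_concentration]
    if len({c for c, _ in pairs}) < 3:
        raise ValueError("steady-state fit needs >= 3 distinct concentrations")
    C = np.array([c for c, _ in pairs])
    R = np.array([r for _, r in pairs])
    if np.all(R <= 0):
        raise ValueError("all equilibrium responses are non-positive")

    x0 = np.log([np.median(C), 1.1 * R.max()])

    def residuals(x):
        kd, rmax = np.exp(x)
        return rmax * C / (C + kd) - R

    sol = optimize.least_squares(residuals, x0, xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15, max_nfev=20000)
    kd, rmax = np.exp(sol.x)
    flags = []
    if kd > 5.0 * C.max():
        flags.append("lower_bound_only")
    if kd < C.min() / 5.0:
        flags.append("saturated")
    return SteadyStateFit(float(kd), float(rmax), float(2.0 * sol.cost),
                          converged=bool(sol.success), flags=flags)
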