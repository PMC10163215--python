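"""1:1 hybridization binding kinetics: sensorgram simulation and global fitting.

The surface reaction ``probe + target <-> duplex`` is treated as an ideal
pseudo-first-order Langmuir system,

    dR/dt = ka * C * (Rmax - R) - kd * R,

whose association phase is ``R(t) = Req * (1 - exp(-kobs * t))`` with
``kobs = ka*C + kd`` and ``Req = Rmax * ka*C / (ka*C + kd)``, and whose
dissociation phase is a single exponential decay ``R0 * exp(-kd * t)``.
Equilibrium constants follow as ``Kd = kd/ka`` and ``Ka = 1/Kd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "InjectionPhase",
    "Sensorgram",
    "FitResult",
    "DEFAULT_SCHEDULE",
    "kd_equilibrium",
    "ka_equilibrium",
    "observed_rate",
    "simulate_association",
    "simulate_dissociation",
    "simulate_sensorgram",
    "fit_1to1",
]


class KineticsDomainError(ValueError):
    """Raised on physically impossible kinetic inputs."""


class ScheduleError(ValueError):
    """Raised on an invalid injection-phase sequence."""


def kd_equilibrium(ka: float, kd: float) -> float:
    """Dissociation equilibrium constant Kd = kd / ka  [M].

    Raises :class:`KineticsDomainError` unless both rate constants are > 0.
    """
    if ka <= 0 or kd <= 0:
        raise KineticsDomainError(f"rate constants must be positive (ka={ka}, kd={kd})")
    return kd / ka


def ka_equilibrium(Kd: float) -> float:
    """Association equilibrium constant Ka = 1 / Kd  [1/M]."""
    if Kd <= 0:
        raise KineticsDomainError(f"Kd must be positive (got {Kd})")
    return 1.0 / Kd


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and saturation response of one probe-sample interaction.

    Attributes
    ----------
    ka : float
        Association rate constant [1/(M s)].
    kd : float
        Dissociation rate constant [1/s].
    rmax : float
        Saturation response [RU].
    """

    ka: float
    kd: float
    rmax: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise KineticsDomainError(
                f"ka, kd, rmax must all be positive "
                f"(ka={self.ka}, kd={self.kd}, rmax={self.rmax})"
            )

    @property
    def Kd(self) -> float:
        """Dissociation equilibrium constant [M]."""
        return kd_equilibrium(self.ka, self.kd)

    @property
    def Ka(self) -> float:
        """Association equilibrium constant [1/M]."""
        return ka_equilibrium(self.Kd)


def observed_rate(params: KineticParams, concentration: float) -> float:
    """Pseudo-first-order observed rate kobs = ka*C + kd  [1/s]."""
    if concentration < 0:
        raise KineticsDomainError(f"concentration must be >= 0 (got {concentration})")
    return params.ka * concentration + params.kd


def equilibrium_response(params: KineticParams, concentration: float) -> float:
    """Plateau response Req = Rmax * ka*C / (ka*C + kd)  [RU]."""
    kac = params.ka * concentration
    return params.rmax * kac / (kac + params.kd)


def simulate_association(
    params: KineticParams,
    concentration: float,
    times: np.ndarray,
    t0: float = 0.0,
) -> np.ndarray:
    """Closed-form association response R(t) = Req * (1 - exp(-kobs*(t - t0)))."""
    if concentration <= 0:
        raise KineticsDomainError(
            f"association requires analyte concentration > 0 (got {concentration})"
        )
    times = np.asarray(times, dtype=float)
    if np.any(times < t0):
        raise KineticsDomainError("times must be >= t0")
    kobs = observed_rate(params, concentration)
    req = equilibrium_response(params, concentration)
    return req * -np.expm1(-kobs * (times - t0))


def simulate_dissociation(
    params: KineticParams,
    r0: float,
    times: np.ndarray,
    t0: float = 0.0,
) -> np.ndarray:
    """Closed-form dissociation response R(t) = R0 * exp(-kd*(t - t0))."""
    if r0 < 0:
        raise KineticsDomainError(f"initial response must be >= 0 (got {r0})")
    times = np.asarray(times, dtype=float)
    if np.any(times < t0):
        raise KineticsDomainError("times must be >= t0")
    return r0 * np.exp(-params.kd * (times - t0))


@dataclass(frozen=True)
class InjectionPhase:
    """One contiguous block of the injection schedule."""

    kind: str  # baseline | association | dissociation | regeneration
    duration: float  # s
    analyte_concentration: float = 0.0  # M; > 0 only during association
    flow_rate: float = 5.0  # uL/min

    KINDS = ("baseline", "association", "dissociation", "regeneration")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ScheduleError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ScheduleError(f"phase duration must be > 0 (got {self.duration})")
        if self.analyte_concentration < 0:
            raise ScheduleError("analyte concentration must be >= 0")
        if (self.kind == "association") != (self.analyte_concentration > 0):
            raise ScheduleError(
                "analyte concentration must be > 0 exactly for association phases"
            )


#: 300 s association / 600 s dissociation hybridization schedule at 100 nM.
DEFAULT_SCHEDULE = (
    InjectionPhase("association", 300.0, analyte_concentration=100e-9),
    InjectionPhase("dissociation", 600.0),
)


@dataclass(frozen=True)
class Sensorgram:
    """A time-resolved SPR response with per-point phase annotations."""

    time: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    phase_labels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        response = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "response", response)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if response.shape != time.shape or len(self.phase_labels) != time.size:
            raise ValueError("time, response and phase_labels must be equal length")
        unknown = set(self.phase_labels) - set(InjectionPhase.KINDS)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")

    def phase_mask(self, kind: str) -> np.ndarray:
        return np.fromiter(
            (label == kind for label in self.phase_labels), dtype=bool, count=len(self.phase_labels)
        )

    def _contiguous_block(self, kind: str) -> slice:
        mask = self.phase_mask(kind)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ScheduleError(f"sensorgram has no {kind} phase")
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ScheduleError(f"{kind} phase is not contiguous")
        return slice(idx[0], idx[-1] + 1)

    def association_block(self) -> slice:
        return self._contiguous_block("association")

    def dissociation_block(self) -> slice:
        return self._contiguous_block("dissociation")


def _validate_schedule(schedule) -> None:
    kinds = [p.kind for p in schedule]
    if "association" not in kinds or "dissociation" not in kinds:
        raise ScheduleError("schedule needs at least one association and one dissociation phase")
    if kinds.index("dissociation") < kinds.index("association"):
        raise ScheduleError("dissociation phase precedes association phase")


def simulate_sensorgram(
    schedule,
    params: KineticParams,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    seed: int | np.random.Generator = 0,
    sampling_hz: float = 1.0,
    metadata: dict | None = None,
) -> Sensorgram:
    """Simulate a full sensorgram over an injection schedule.

    The noise-free trajectory is the piecewise closed form of the 1:1 model,
    continuous across phase boundaries (each phase starts from the response
    reached at the end of the previous one; regeneration resets to baseline).
    Additive i.i.d. Gaussian noise of standard deviation ``noise_sd`` RU and
    a linear drift of ``drift`` RU/s are then applied.  ``seed`` is mandatory
    in spirit: the default 0 gives a reproducible trace.
    """
    schedule = tuple(schedule)
    _validate_schedule(schedule)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    times, clean, labels = [], [], []
    t_start, r_current = 0.0, 0.0
    for phase in schedule:
        n = max(int(round(phase.duration * sampling_hz)), 2)
        t = t_start + np.linspace(0.0, phase.duration, n, endpoint=False)
        if phase.kind == "association":
            # exact relaxation toward Req from the current response; reduces to
            # Req*(1-exp(-kobs t)) when the phase starts at baseline
            kobs = observed_rate(params, phase.analyte_concentration)
            req = equilibrium_response(params, phase.analyte_concentration)
            r = req + (r_current - req) * np.exp(-kobs * (t - t_start))
            r_current_end = r[-1]
        elif phase.kind == "dissociation":
            r = simulate_dissociation(params, r_current, t, t0=t_start)
            r_current_end = r[-1]
        elif phase.kind == "baseline":
            r = np.full_like(t, r_current)
            r_current_end = r_current
        else:  # regeneration strips the duplex back to baseline
            r = r_current * np.exp(-(t - t_start) / max(phase.duration / 6.0, 1e-9))
            r_current_end = 0.0
        times.append(t)
        clean.append(r)
        labels.extend([phase.kind] * n)
        t_start += phase.duration
        r_current = r_current_end if phase.kind != "regeneration" else 0.0

    time = np.concatenate(times)
    response = np.concatenate(clean) + drift * time
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=time.size)
    meta = dict(metadata or {})
    meta.setdefault("noise_sd", noise_sd)
    meta.setdefault("drift", drift)
    return Sensorgram(time, response, tuple(labels), metadata=meta)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a global 1:1 fit over association + dissociation."""

    estimate: KineticParams | None
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_points: int
    init: dict[str, float]
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            assert self.estimate is not None
            for v in (self.estimate.ka, self.estimate.kd, self.estimate.rmax):
                if not np.isfinite(v) or v <= 0:
                    raise ValueError("converged fit must carry positive finite estimates")


_LOG_BOUNDS = {
    "ka": (np.log(1e-2), np.log(1e12)),
    "kd": (np.log(1e-8), np.log(1e2)),
}


def _initial_guess(t_a, r_a, t_d, r_d, concentration):
    """Derivative-free initializers from log-linearized phase tails."""
    eps = 1e-12
    # kd0: OLS of ln R over the last half of the dissociation block
    half = r_d[len(r_d) // 2 :]
    th = t_d[len(t_d) // 2 :]
    pos = half > eps
    if pos.sum() >= 2:
        slope = np.polyfit(th[pos], np.log(half[pos]), 1)[0]
        kd0 = max(-slope, 1e-6)
    else:
        kd0 = 1e-3
    # kobs0: OLS of ln(Req_hat - R) over the association block
    req_hat = float(np.max(r_a)) if r_a.size else 0.0
    gap = req_hat * 1.001 - r_a
    pos = gap > eps
    if pos.sum() >= 2:
        slope = np.polyfit(t_a[pos], np.log(gap[pos]), 1)[0]
        kobs0 = max(-slope, 1e-6)
    else:
        kobs0 = 1e-2
    ka0 = max((kobs0 - kd0) / concentration, 1e-2)
    rmax0 = req_hat * (ka0 * concentration + kd0) / max(ka0 * concentration, eps)
    rmax0 = min(max(rmax0, req_hat, eps), 10.0 * max(req_hat, eps))
    return {"ka": ka0, "kd": kd0, "rmax": rmax0}


def _model_responses(theta_log, t_a, t_d, concentration, t_d0):
    ka, kd, rmax = np.exp(theta_log)
    kobs = ka * concentration + kd
    req = rmax * ka * concentration / kobs
    r_a = req * -np.expm1(-kobs * t_a)
    # dissociation decays from the response at the association/dissociation boundary
    r0 = req * -np.expm1(-kobs * t_d0)
    r_d = r0 * np.exp(-kd * (t_d - t_d0))
    return r_a, r_d


def fit_1to1(
    sensorgram: Sensorgram,
    concentration: float,
    max_nfev: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Global weighted least-squares fit of (ka, kd, Rmax) to both phases.

    Parameters are optimized in log space with positivity-enforcing bounds;
    standard errors come from the Gauss-Newton approximation of the Hessian
    at the optimum (propagated back from log space via the delta method).
    Non-convergence after bounded restarts yields ``converged=False`` rather
    than an exception.
    """
    if concentration <= 0:
        raise KineticsDomainError(f"concentration must be > 0 (got {concentration})")
    a = sensorgram.association_block()
    d = sensorgram.dissociation_block()
    t_a = sensorgram.time[a]
    r_a = sensorgram.response[a]
    t_d = sensorgram.time[d]
    r_d = sensorgram.response[d]
    if t_a.size < 10 or t_d.size < 10:
        raise ValueError("need >= 10 points in each of association and dissociation")
    t0_a = t_a[0]
    t_a = t_a - t0_a
    t_d = t_d - t0_a
    t_d0 = t_d[0]
    n_points = t_a.size + t_d.size

    max_r = float(np.max(np.abs(sensorgram.response)))
    if max_r < 1e-9:  # flat trace: ka/kd/Rmax unidentifiable
        return FitResult(
            estimate=None,
            stderr={},
            rss=float(np.sum(r_a**2) + np.sum(r_d**2)),
            converged=False,
            n_points=n_points,
            init={},
            message="degenerate flat trace; parameters unidentifiable",
        )

    init = _initial_guess(t_a, r_a, t_d, r_d, concentration)
    y = np.concatenate([r_a, r_d])

    def residuals(theta_log):
        m_a, m_d = _model_responses(theta_log, t_a, t_d, concentration, t_d0)
        return np.concatenate([m_a, m_d]) - y

    lo = np.array([_LOG_BOUNDS["ka"][0], _LOG_BOUNDS["kd"][0], np.log(1e-9)])
    hi = np.array([_LOG_BOUNDS["ka"][1], _LOG_BOUNDS["kd"][1], np.log(10.0 * max_r)])
    rng = np.random.default_rng(seed)

    starts = [np.log([init["ka"], init["kd"], init["rmax"]])]
    for _ in range(n_restarts):
        starts.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, size=3))
    starts = [np.clip(s, lo + 1e-9, hi - 1e-9) for s in starts]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception:  # numerical failure in one start is not fatal
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-20:
            break

    if best is None or not np.all(np.isfinite(best.x)):
        return FitResult(None, {}, np.inf, False, n_points, init, "optimizer failed")

    ka, kd, rmax = np.exp(best.x)
    rss = float(2.0 * best.cost)
    dof = max(n_points - 3, 1)
    sigma2 = rss / dof
    # covariance in log space from J^T J; delta method back to linear scale
    try:
        jtj = best.jac.T @ best.jac
        cov_log = sigma2 * np.linalg.pinv(jtj)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
        stderr = {
            "ka": float(ka * se_log[0]),
            "kd": float(kd * se_log[1]),
            "rmax": float(rmax * se_log[2]),
        }
    except np.linalg.LinAlgError:
        stderr = {}

    estimate = KineticParams(ka=float(ka), kd=float(kd), rmax=float(rmax))
    return FitResult(
        estimate=estimate,
        stderr=stderr,
        rss=rss,
        converged=True,
        n_points=n_points,
        init=init,
        message=best.message,
    )
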