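"""QCM-D trace simulation and dissipation-versus-frequency slope analysis.

The gravimetric genotyping readout is the slope of the dissipation shift
plotted against the frequency shift for one overtone: a hybrid layer that is
as rigid and well-packed as the reference full duplex produces the same
slope; a floppier partial hybrid changes it.  A call compares a sample's
overall slope with the reference curve's within explicit tolerance bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotyping import GenotypeCall
from .spr import KineticParams, simulate_sensorgram

__all__ = [
    "QcmdTrace",
    "DfDdCurve",
    "QcmdCallParams",
    "FUNDAMENTAL_HZ",
    "C_SAUERBREY",
    "simulate_qcmd_trace",
    "sauerbrey_mass",
    "df_dd_slopes",
    "qcmd_call",
    "calibrate_call_params",
]

#: AT-cut crystal fundamental [Hz].
FUNDAMENTAL_HZ = 4.95e6

#: Sauerbrey mass sensitivity for a 5 MHz AT-cut crystal [ng cm^-2 Hz^-1];
#: conventional approximation for the 4.95 MHz fundamental.
C_SAUERBREY = 17.7

#: Frequency shift of a saturated layer at the fundamental [Hz] and the
#: baseline dissipation-per-frequency coefficient of a rigid layer
#: [1e-6 dissipation units per Hz].  Simulation constants, not measurements.
F_LOAD_HZ = 12.0
S_RIGID = 0.02

DEFAULT_OVERTONE = 3


class QcmdDataError(ValueError):
    """Raised on malformed QCM-D inputs."""


@dataclass(frozen=True)
class QcmdTrace:
    """Time-resolved frequency and dissipation shifts per overtone.

    ``delta_f`` maps overtone number n (odd) to the raw frequency shift
    series in Hz (negative under mass loading); ``delta_D`` maps n to the
    dissipation shift in units of 1e-6.
    """

    time: np.ndarray
    delta_f: dict[int, np.ndarray]
    delta_D: dict[int, np.ndarray]
    fundamental_frequency: float = FUNDAMENTAL_HZ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "time", time)
        if not self.delta_f:
            raise QcmdDataError("overtone set must be non-empty")
        if set(self.delta_f) != set(self.delta_D):
            raise QcmdDataError("delta_f and delta_D overtone sets differ")
        for n in self.delta_f:
            if n % 2 == 0 or n <= 0:
                raise QcmdDataError(f"overtones must be odd positive (got {n})")
            if len(self.delta_f[n]) != time.size or len(self.delta_D[n]) != time.size:
                raise QcmdDataError("series length must match the time grid")

    @property
    def overtones(self) -> tuple[int, ...]:
        return tuple(sorted(self.delta_f))


def simulate_qcmd_trace(
    params: KineticParams,
    concentration: float,
    layer_softness: float,
    schedule,
    noise_sd_f: float = 0.0,
    noise_sd_D: float = 0.0,
    seed: int | np.random.Generator = 0,
    overtones: tuple[int, ...] = (3, 5, 7),
    sampling_hz: float = 1.0,
    metadata: dict | None = None,
) -> QcmdTrace:
    """Simulate hybridization Δf/ΔD traces driven by 1:1 binding occupancy.

    Fractional occupancy θ(t) follows the same kinetics as the SPR
    simulator.  Per overtone n, ``Δf_n = -F_LOAD_HZ * n * θ(t)`` (Sauerbrey
    scaling) and ``ΔD_n = S_RIGID * (1 + layer_softness) * |Δf_n|``, so the
    noise-free ΔD-vs-Δf relation is exactly linear with a slope magnitude of
    ``S_RIGID * (1 + layer_softness)``.
    """
    if layer_softness < 0:
        raise QcmdDataError(f"layer_softness must be >= 0 (got {layer_softness})")
    if noise_sd_f < 0 or noise_sd_D < 0:
        raise QcmdDataError("noise standard deviations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sensorgram = simulate_sensorgram(
        schedule, params, noise_sd=0.0, drift=0.0, seed=0, sampling_hz=sampling_hz
    )
    theta = sensorgram.response / params.rmax

    slope = S_RIGID * (1.0 + layer_softness)
    delta_f, delta_D = {}, {}
    for n in overtones:
        df_clean = -F_LOAD_HZ * n * theta
        dd_clean = slope * np.abs(df_clean)
        df = df_clean + (rng.normal(0.0, noise_sd_f, theta.size) if noise_sd_f else 0.0)
        dd = dd_clean + (rng.normal(0.0, noise_sd_D, theta.size) if noise_sd_D else 0.0)
        delta_f[n] = df
        delta_D[n] = dd
    meta = dict(metadata or {})
    meta.setdefault("layer_softness", layer_softness)
    meta.setdefault("concentration_M", concentration)
    return QcmdTrace(sensorgram.time, delta_f, delta_D, metadata=meta)


def sauerbrey_mass(delta_f: float | np.ndarray, overtone: int) -> float | np.ndarray:
    """Areal mass [ng/cm^2] from a rigid-film frequency shift: -C * Δf / n."""
    if overtone <= 0 or overtone % 2 == 0:
        raise QcmdDataError(f"overtone must be odd positive (got {overtone})")
    return -C_SAUERBREY * np.asarray(delta_f, dtype=float) / overtone


@dataclass(frozen=True)
class DfDdCurve:
    """Ordered (Δf, ΔD) pairs for one overtone with a piecewise-linear fit."""

    delta_f: np.ndarray
    delta_D: np.ndarray
    segment_boundaries: tuple[int, ...]  # start indices, first always 0
    segment_slopes: tuple[float, ...]
    overall_slope: float

    def __post_init__(self) -> None:
        if len(self.segment_boundaries) != len(self.segment_slopes):
            raise QcmdDataError("one slope per segment required")
        if list(self.segment_boundaries) != sorted(set(self.segment_boundaries)):
            raise QcmdDataError("segment boundaries must be strictly increasing")


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x; 0 for degenerate x."""
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def _segment_cost_table(x: np.ndarray, y: np.ndarray, min_len: int) -> np.ndarray:
    """SSE of a linear fit on every window [i, j); inf below min_len."""
    n = x.size
    one = np.ones(n)
    cs = {
        "n": np.concatenate([[0.0], np.cumsum(one)]),
        "x": np.concatenate([[0.0], np.cumsum(x)]),
        "y": np.concatenate([[0.0], np.cumsum(y)]),
        "xx": np.concatenate([[0.0], np.cumsum(x * x)]),
        "xy": np.concatenate([[0.0], np.cumsum(x * y)]),
        "yy": np.concatenate([[0.0], np.cumsum(y * y)]),
    }
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            m = cs["n"][j] - cs["n"][i]
            sx = cs["x"][j] - cs["x"][i]
            sy = cs["y"][j] - cs["y"][i]
            sxx = cs["xx"][j] - cs["xx"][i]
            sxy = cs["xy"][j] - cs["xy"][i]
            syy = cs["yy"][j] - cs["yy"][i]
            den = m * sxx - sx * sx
            if den <= 0:  # vertical or duplicated x: fall back to variance of y
                cost[i, j] = syy - sy * sy / m
                continue
            beta = (m * sxy - sx * sy) / den
            alpha = (sy - beta * sx) / m
            sse = syy - 2 * alpha * sy - 2 * beta * sxy + m * alpha**2 + 2 * alpha * beta * sx + beta**2 * sxx
            cost[i, j] = max(sse, 0.0)
    return cost


def df_dd_slopes(
    trace: QcmdTrace,
    overtone: int = DEFAULT_OVERTONE,
    n_segments: int = 1,
    min_segment_len: int = 5,
) -> DfDdCurve:
    """Piecewise-linear segmentation of ΔD against Δf for one overtone.

    Contiguous segments are chosen by dynamic programming to minimize the
    total squared error of per-segment least-squares lines; the overall
    slope comes from one global fit over all points.
    """
    if overtone not in trace.delta_f:
        raise QcmdDataError(f"trace has no overtone {overtone}")
    x = np.asarray(trace.delta_f[overtone], dtype=float)
    y = np.asarray(trace.delta_D[overtone], dtype=float)
    n = x.size
    if n_segments < 1:
        raise QcmdDataError("n_segments must be >= 1")
    if n < min_segment_len * n_segments:
        raise QcmdDataError(
            f"need >= {min_segment_len * n_segments} points for {n_segments} segments (got {n})"
        )

    cost = _segment_cost_table(x, y, min_segment_len)
    # dp[k][j]: best cost covering [0, j) with k segments
    dp = np.full((n_segments + 1, n + 1), np.inf)
    back = np.zeros((n_segments + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, n_segments + 1):
        for j in range(k * min_segment_len, n + 1):
            cand = dp[k - 1, : j - min_segment_len + 1] + cost[: j - min_segment_len + 1, j]
            i = int(np.argmin(cand))
            dp[k, j] = cand[i]
            back[k, j] = i
    if not np.isfinite(dp[n_segments, n]):
        raise QcmdDataError("no feasible segmentation")

    bounds = []
    j = n
    for k in range(n_segments, 0, -1):
        i = back[k, j]
        bounds.append(i)
        j = i
    bounds = tuple(sorted(bounds))

    slopes = []
    edges = list(bounds) + [n]
    for i, j in zip(edges[:-1], edges[1:]):
        slopes.append(_ls_slope(x[i:j], y[i:j]))
    return DfDdCurve(
        delta_f=x,
        delta_D=y,
        segment_boundaries=bounds,
        segment_slopes=tuple(slopes),
        overall_slope=_ls_slope(x, y),
    )


@dataclass(frozen=True)
class QcmdCallParams:
    """Tolerance bands for the slope-comparison call."""

    tol_positive: float = 0.15
    tol_ambiguous: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.tol_positive < self.tol_ambiguous):
            raise QcmdDataError("require 0 < tol_positive < tol_ambiguous")


def qcmd_call(
    sample_curve: DfDdCurve,
    reference_curve: DfDdCurve,
    call_params: QcmdCallParams = QcmdCallParams(),
    sample_id: str = "",
    mutation_panel: str = "",
) -> GenotypeCall:
    """Call a sample by comparing overall slopes against the reference curve.

    With relative slope difference ``r = |s - s_ref| / |s_ref|``: positive if
    ``r <= tol_positive``, ambiguous if ``r <= tol_ambiguous``, else negative.
    """
    s_ref = reference_curve.overall_slope
    if s_ref == 0:
        raise QcmdDataError("reference curve has zero overall slope")
    s = sample_curve.overall_slope
    r = abs(s - s_ref) / abs(s_ref)
    if r <= call_params.tol_positive:
        call = "positive"
    elif r <= call_params.tol_ambiguous:
        call = "ambiguous"
    else:
        call = "negative"
    return GenotypeCall(
        sample_id=sample_id,
        mutation_panel=mutation_panel,
        assay="QCMD",
        call=call,
        evidence=r,
    )


def calibrate_call_params(
    relative_diffs: np.ndarray,
    truth_positive: np.ndarray,
    grid: np.ndarray | None = None,
) -> QcmdCallParams:
    """Tune the positive tolerance to maximize balanced accuracy on labels.

    ``relative_diffs`` are slope ratios r per sample; ``truth_positive`` the
    matching boolean labels.  The ambiguous band keeps its default width
    ratio above the tuned positive tolerance.
    """
    r = np.asarray(relative_diffs, dtype=float)
    t = np.asarray(truth_positive, dtype=bool)
    if r.shape != t.shape or r.size == 0:
        raise QcmdDataError("relative_diffs and truth_positive must align and be non-empty")
    if grid is None:
        grid = np.unique(np.concatenate([r, [0.05, 0.15, 0.25]]))
    best_tol, best_score = 0.15, -1.0
    for tol in grid:
        if tol <= 0:
            continue
        pred = r <= tol
        tpr = pred[t].mean() if t.any() else 1.0
        tnr = (~pred[~t]).mean() if (~t).any() else 1.0
        score = 0.5 * (tpr + tnr)
        if score > best_score:
            best_score, best_tol = score, float(tol)
    return QcmdCallParams(tol_positive=best_tol, tol_ambiguous=best_tol * (0.35 / 0.15))
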