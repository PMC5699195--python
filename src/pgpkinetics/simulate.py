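"""Scenario engine: steady states, dose sweeps, knockouts, transition points.

Readout convention: cytosolic substrate (paclitaxel) concentration, by
default at steady state.  Steady states are found by integrating the stiff
system in growing chunks and, after each chunk, attempting a Newton polish
of the algebraic system ``rhs(y) = 0`` with the pump-conservation constraint
substituted for one redundant pump equation.  The polish is accepted only if
it stays close to the integrated trajectory, keeps every concentration
nonnegative and satisfies the stationarity criterion; otherwise integration
continues (hard cap ``t_max``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, IntegrationError, InvalidInputError
from .pgp_model import (
    ATP_CYT,
    PGP_OFFSET,
    SUB_CYT,
    SUB_EXT,
    TKI_EXT,
    DEFAULT_KD_ATP,
    KineticParameters,
    ReactionNetwork,
    build_network,
    n_variables,
)
from .thermo import DrugParams

__all__ = [
    "Mechanism",
    "Scenario",
    "SweepResult",
    "SolverSettings",
    "TransitionPoint",
    "run_scenario",
    "dose_response",
    "transition_point",
    "improvement_screen",
    "steady_state",
]

STEADY_STATE = "steady_state"

#: Parameters a hypothetical-improvement scenario may act on.
IMPROVABLE = ("Kd_nbd", "Kd_sbd", "PC")

_SWEEP_AXES = ("tki_ext", "pac_ext", "atp", "pgp_total")


class Mechanism(Enum):
    """Which TKI binding routes are active (knockouts via infinite Kd)."""

    BOTH = "both"
    NBD_ONLY = "nbd_only"  # Kd_N -> inf: no TKI binding at the SBD
    SBD_ONLY = "sbd_only"  # Kd_I -> inf: no TKI binding at the NBD
    NEITHER = "neither"  # TKI inert at both sites (control)


@dataclass(frozen=True)
class SolverSettings:
    """Integrator and steady-state tolerances."""

    rtol: float = 1e-8
    atol: float = 1e-12
    method: str = "BDF"  # LSODA stalls on the stiffest corners of this system
    t_chunk: float = 2000.0  # first integration chunk, s
    t_max: float = 1e6  # hard cap on simulated time, s
    # Stationarity: |dy_i| <= ss_rate_rtol*|y_i| + ss_flux_rtol*gross_i + atol.
    # The gross-flux term absorbs roundoff from near-cancelling fluxes.
    ss_rate_rtol: float = 1e-8
    ss_flux_rtol: float = 1e-11
    ss_rate_atol: float = 1e-20


DEFAULT_SETTINGS = SolverSettings()


@dataclass(frozen=True)
class Scenario:
    """Initial/clamped concentrations, mechanism toggles and sweep definition."""

    substrate: str = "paclitaxel"
    tki: str | None = "nilotinib"
    pac_ext: float = 3e-6
    tki_ext: float = 0.0
    atp: float = 3e-3
    pgp_total: float = 10e-6
    mechanism: Mechanism = Mechanism.BOTH
    sweep: tuple[str, tuple[float, ...]] | None = None
    readout_time: float | str = STEADY_STATE
    improvement: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        for label in ("pac_ext", "tki_ext", "atp", "pgp_total"):
            if getattr(self, label) < 0:
                raise InvalidInputError(f"{label} must be >= 0")
        if self.sweep is not None:
            axis, values = self.sweep
            if axis not in _SWEEP_AXES:
                raise InvalidInputError(f"sweep axis must be one of {_SWEEP_AXES}")
            values = tuple(float(v) for v in values)
            if not values or any(v <= 0 for v in values):
                raise InvalidInputError("sweep values must be positive")
            if list(values) != sorted(values):
                raise InvalidInputError("sweep values must be sorted ascending")
            object.__setattr__(self, "sweep", (axis, values))
        if self.improvement is not None:
            param, fold = self.improvement
            if param not in IMPROVABLE:
                raise InvalidInputError(f"improvement parameter must be in {IMPROVABLE}")
            if not (fold > 0):
                raise InvalidInputError("improvement fold must be > 0")
        if self.readout_time != STEADY_STATE and not (float(self.readout_time) > 0):
            raise InvalidInputError("readout_time must be positive or STEADY_STATE")


@dataclass
class SweepResult:
    """Endpoint readouts along one sweep axis."""

    axis: str
    values: np.ndarray
    readouts: np.ndarray  # cytosolic substrate, molar
    states: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.readouts = np.asarray(self.readouts, dtype=float)
        if self.values.shape != self.readouts.shape:
            raise InvalidInputError("one readout per sweep value required")


@dataclass(frozen=True)
class TransitionPoint:
    """ATP level where the NBD- and SBD-only readout curves cross."""

    atp: float | None
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# Parameter assembly


def _tki_params(scenario: Scenario, drugs: Mapping[str, DrugParams]) -> DrugParams:
    try:
        tki = drugs[scenario.tki] if scenario.tki else None
    except KeyError as exc:
        raise ConfigurationError(f"unknown TKI name: {scenario.tki!r}") from exc
    if tki is None:
        # sentinel inert compound so the TKI slots exist but carry no flux
        return DrugParams("none", None, 1.0, math.inf)
    if scenario.improvement is not None:
        param, fold = scenario.improvement
        if param == "Kd_nbd":
            tki = replace(tki, Kd_nbd=tki.Kd_nbd / fold)
        elif param == "Kd_sbd":
            tki = replace(tki, Kd_sbd_membrane=tki.Kd_sbd_membrane / fold)
        else:  # PC: partitioning only; the membrane-phase Kd is held fixed
            tki = replace(
                tki,
                partition_coefficient=tki.partition_coefficient * fold,
                Kd_sbd_membrane=tki.Kd_sbd_membrane,
            )
    return tki


def scenario_params(
    scenario: Scenario,
    drugs: Mapping[str, DrugParams],
    base: KineticParameters | None = None,
) -> KineticParameters:
    """Translate a scenario + drug table into :class:`KineticParameters`."""
    try:
        sub = drugs[scenario.substrate]
    except KeyError as exc:
        raise ConfigurationError(f"unknown substrate name: {scenario.substrate!r}") from exc
    tki = _tki_params(scenario, drugs)
    kd_atp = drugs["atp"].Kd_nbd if "atp" in drugs else DEFAULT_KD_ATP
    kd_n, kd_i = tki.Kd_sbd_membrane, tki.Kd_nbd
    if scenario.mechanism in (Mechanism.NBD_ONLY, Mechanism.NEITHER):
        kd_n = math.inf
    if scenario.mechanism in (Mechanism.SBD_ONLY, Mechanism.NEITHER):
        kd_i = math.inf
    kwargs = dict(
        Kd_P=sub.Kd_sbd_membrane,
        Kd_N=kd_n,
        Kd_A=kd_atp,
        Kd_I=kd_i,
        k_passive_sub=sub.passive_rate,
        k_passive_tki=tki.passive_rate,
        pc_sub=sub.partition_coefficient,
        pc_tki=tki.partition_coefficient,
    )
    if base is not None:
        for label in ("k_on_sbd", "k_on_nbd", "k_cat", "V_ext", "V_mem", "V_cyt",
                      "extracellular_clamped", "atp_clamped"):
            kwargs[label] = getattr(base, label)
    return KineticParameters(**kwargs)


def initial_vector(
    scenario: Scenario, noncompetitive: bool = False
) -> np.ndarray:
    """Default initial condition: drugs extracellular, pump all empty."""
    y0 = np.zeros(n_variables(noncompetitive))
    y0[SUB_EXT] = scenario.pac_ext
    y0[TKI_EXT] = scenario.tki_ext
    y0[ATP_CYT] = scenario.atp
    y0[PGP_OFFSET] = scenario.pgp_total  # (EMPTY, EMPTY) is the first state
    return y0


# ---------------------------------------------------------------------------
# Steady-state machinery


def _is_stationary(net: ReactionNetwork, y: np.ndarray, settings: SolverSettings) -> bool:
    dy = net.rhs(0.0, y)
    return bool(np.all(np.abs(dy) <= _ss_tolerance(net, y, settings)))


def _ss_tolerance(net: ReactionNetwork, y: np.ndarray, settings: SolverSettings) -> np.ndarray:
    return (
        settings.ss_rate_rtol * np.abs(y)
        + settings.ss_flux_rtol * net.gross_flux(y)
        + settings.ss_rate_atol
    )


def _newton_polish(
    net: ReactionNetwork,
    y: np.ndarray,
    pgp_idx: np.ndarray,
    pgp_total: float,
    settings: SolverSettings,
    max_iter: int = 60,
) -> np.ndarray | None:
    """Damped Newton solve of rhs(y)=0 in log-concentration space.

    The log parameterization keeps every concentration positive and evens out
    the many orders of magnitude between variables.  One redundant
    pump-state equation is replaced by the conservation constraint.  Returns
    the stationary point, or None when the current iterate is not yet inside
    the Newton basin (the caller then integrates further).
    """
    free = np.ones(net.n_vars, dtype=bool)
    free[net.clamped] = False
    y = y.copy()
    dy0 = net.rhs(0.0, y)
    tol0 = _ss_tolerance(net, y, settings)
    zero = y == 0.0
    # Zero variables with nonzero inflow (often artifacts of clipping tiny
    # negative solver output) are seeded just above zero so the log-space
    # iteration can lift them; zeros with zero inflow (knocked-out states,
    # absent pump) stay fixed at zero.
    seed = zero & free & (np.abs(dy0) > tol0)
    if np.any(seed):
        y[seed] = 1e-16 * max(float(np.max(y)), 1e-30)
        zero = y == 0.0
    free &= ~zero
    free_idx = np.flatnonzero(free)
    if free_idx.size == 0:
        return y.copy() if _is_stationary(net, y, settings) else None

    in_pgp = np.isin(free_idx, pgp_idx)
    ref_pos = int(np.argmax(in_pgp)) if bool(np.any(in_pgp)) else -1
    cons_scale = 1e-6 * max(pgp_total, 1e-12)  # conservation residual weight
    y_fixed = y.copy()

    def assemble(u: np.ndarray) -> np.ndarray:
        yf = y_fixed.copy()
        yf[free_idx] = np.exp(u)
        return yf

    def residual(yf: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        F = net.rhs(0.0, yf)[free_idx]
        tolv = _ss_tolerance(net, yf, settings)[free_idx]
        if ref_pos >= 0:
            F[ref_pos] = yf[pgp_idx].sum() - pgp_total
            tolv[ref_pos] = cons_scale
        return F, tolv, float(np.max(np.abs(F) / tolv))

    u = np.log(y[free_idx])
    yf = assemble(u)
    F, tolv, wnorm = residual(yf)
    for _ in range(max_iter):
        if wnorm < 1.0:
            y_ss = yf.copy()
            if _is_stationary(net, y_ss, settings) and (
                abs(y_ss[pgp_idx].sum() - pgp_total) <= max(cons_scale, 1e-30)
            ):
                return y_ss
            return None
        J = net.jac(0.0, yf)[np.ix_(free_idx, free_idx)] * yf[free_idx][None, :]
        if ref_pos >= 0:
            J[ref_pos] = np.where(in_pgp, yf[free_idx], 0.0)
        try:
            delta = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(delta)):
            return None
        delta = np.clip(delta, -4.0, 4.0)  # cap steps at e^4 per iteration
        alpha, improved = 1.0, False
        while alpha > 1e-4:
            u_try = u + alpha * delta
            yf_try = assemble(u_try)
            F_try, tolv_try, wnorm_try = residual(yf_try)
            if wnorm_try < wnorm:
                u, yf, F, tolv, wnorm = u_try, yf_try, F_try, tolv_try, wnorm_try
                improved = True
                break
            alpha *= 0.5
        if not improved:
            return None
    return None


def integrate(
    net: ReactionNetwork,
    y0: np.ndarray,
    t_span: tuple[float, float],
    settings: SolverSettings = DEFAULT_SETTINGS,
    t_eval: Sequence[float] | None = None,
):
    """Integrate the network over ``t_span`` (thin wrapper over solve_ivp)."""
    sol = solve_ivp(
        net.rhs,
        t_span,
        np.asarray(y0, dtype=float),
        method=settings.method,
        jac=net.jac,
        rtol=settings.rtol,
        atol=settings.atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    return sol

def steady_state(
    net: ReactionNetwork,
    y0: np.ndarray,
    pgp_idx: np.ndarray,
    settings: SolverSettings = DEFAULT_SETTINGS,
    y_guess: np.ndarray | None = None,
) -> np.ndarray:
    """Steady state of the clamped system reached from ``y0``.

    ``y_guess`` (e.g. the steady state of a neighbouring sweep point) is
    tried as a direct Newton starting point before any integration.
    """
    y0 = np.asarray(y0, dtype=float)
    pgp_total = float(y0[pgp_idx].sum())
    y = y0.copy()
    if _is_stationary(net, y, settings):
        return y
    clamped = net.clamped

    def _accept(candidate: np.ndarray | None) -> np.ndarray | None:
        if candidate is None:
            return None
        if clamped.size:  # clamp contract: bit-identical to initial values
            candidate[clamped] = y0[clamped]
        return candidate

    if y_guess is not None and y_guess.shape == y0.shape:
        g = np.maximum(np.asarray(y_guess, dtype=float), 0.0)
        g[clamped] = y0[clamped]
        total = g[pgp_idx].sum()
        if total > 0 and pgp_total > 0:
            g[pgp_idx] *= pgp_total / total  # restore conservation
        elif pgp_total == 0:
            g[pgp_idx] = 0.0
        else:
            g[pgp_idx] = 0.0
            g[pgp_idx[0]] = pgp_total
        polished = _accept(_newton_polish(net, g, pgp_idx, pgp_total, settings))
        if polished is not None:
            return polished

    t_elapsed, chunk = 0.0, settings.t_chunk
    while True:
        try:
            sol = integrate(net, y, (0.0, chunk), settings)
        except IntegrationError:
            if settings.method == "BDF":
                raise
            # stiff-corner fallback: retry the chunk with the implicit method
            sol = integrate(net, y, (0.0, chunk), replace(settings, method="BDF"))
        y = np.maximum(sol.y[:, -1], 0.0)
        if clamped.size:
            y[clamped] = y0[clamped]
        polished = _accept(_newton_polish(net, y, pgp_idx, pgp_total, settings))
        if polished is not None:
            return polished
        t_elapsed += chunk
        if t_elapsed >= settings.t_max:
            if _is_stationary(net, y, settings):
                return y
            raise IntegrationError(
                f"no steady state within t_max={settings.t_max:g} s"
            )
        # cap chunk length: the implicit solver can grind near-stationary
        # stretches, and each chunk boundary is another polish opportunity
        chunk = min(chunk * 4.0, 6.4e4, settings.t_max - t_elapsed)


# ---------------------------------------------------------------------------
# Scenario drivers


def _endpoint(
    scenario: Scenario,
    drugs: Mapping[str, DrugParams],
    base: KineticParameters | None,
    settings: SolverSettings,
    y_guess: np.ndarray | None = None,
) -> np.ndarray:
    params = scenario_params(scenario, drugs, base)
    net = build_network(params)
    y0 = initial_vector(scenario)
    idx = np.arange(PGP_OFFSET, n_variables(False))
    if scenario.readout_time == STEADY_STATE:
        return steady_state(net, y0, idx, settings, y_guess=y_guess)
    # fixed-time readout: integrate in bounded chunks and stop early once
    # stationary (the implicit solver can grind on long quiescent stretches)
    remaining = float(scenario.readout_time)
    y = y0.copy()
    while remaining > 0.0:
        chunk = min(remaining, 6.4e4)
        sol = integrate(net, y, (0.0, chunk), settings)
        y = np.maximum(sol.y[:, -1], 0.0)
        y[net.clamped] = y0[net.clamped]
        remaining -= chunk
        if remaining > 0.0 and _is_stationary(net, y, settings):
            break
    return y


def run_scenario(
    scenario: Scenario,
    drugs: Mapping[str, DrugParams],
    base: KineticParameters | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> SweepResult:
    """Run one scenario, sweeping its axis if defined.

    Returns cytosolic substrate concentration per sweep value (a single-point
    sweep over the scenario's own TKI dose when no sweep is defined).
    """
    if scenario.sweep is None:
        axis, values = "tki_ext", (scenario.tki_ext,)
        sweeps = [scenario]
    else:
        axis, values = scenario.sweep
        sweeps = [
            replace(scenario, sweep=None, **{axis: v}) for v in values
        ]
    readouts, states = [], []
    y_prev: np.ndarray | None = None
    for scn, v in zip(sweeps, values):
        try:
            y = _endpoint(scn, drugs, base, settings, y_guess=y_prev)
        except IntegrationError as exc:
            raise IntegrationError(
                f"scenario failed at {axis}={v:g}: {exc}", sweep_value=float(v)
            ) from exc
        readouts.append(float(y[SUB_CYT]))
        states.append(y)
        y_prev = y  # warm-start the next sweep point
    return SweepResult(axis, np.asarray(values), np.asarray(readouts), states)


def dose_response(
    tki: str,
    doses: Sequence[float],
    pgp_levels: Sequence[float],
    base: Scenario,
    drugs: Mapping[str, DrugParams],
    params: KineticParameters | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> dict[float, SweepResult]:
    """TKI dose-response curves of substrate accumulation, per pump level."""
    doses = tuple(float(d) for d in doses)
    if not doses or any(d <= 0 for d in doses) or list(doses) != sorted(doses):
        raise InvalidInputError("doses must be positive and sorted ascending")
    out: dict[float, SweepResult] = {}
    for level in pgp_levels:
        scn = replace(base, tki=tki, pgp_total=float(level), sweep=("tki_ext", doses))
        out[float(level)] = run_scenario(scn, drugs, params, settings)
    return out


def _mechanism_readout(
    mechanism: Mechanism,
    atp: float,
    base: Scenario,
    drugs: Mapping[str, DrugParams],
    params: KineticParameters | None,
    settings: SolverSettings,
) -> float:
    scn = replace(base, mechanism=mechanism, atp=float(atp), sweep=None)
    return float(run_scenario(scn, drugs, params, settings).readouts[0])


def transition_point(
    tki: str,
    atp_values: Sequence[float],
    base: Scenario,
    drugs: Mapping[str, DrugParams],
    params: KineticParameters | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    rel_tol: float = 0.01,
) -> TransitionPoint:
    """ATP level where the SBD-only mechanism overtakes the NBD-only one.

    Scans a log grid for a sign change of (NBD-only minus SBD-only) readout,
    then bisects on log-ATP until the bracket width is below ``rel_tol``.
    Multiple crossings return the lowest with the ambiguity flag set; nearly
    identical curves (no resolvable difference) are flagged ambiguous with no
    crossing value.
    """
    atp_values = np.asarray(sorted(float(a) for a in atp_values))
    if atp_values.size < 2 or atp_values[0] <= 0:
        raise InvalidInputError("need >= 2 positive ATP grid values")
    base = replace(base, tki=tki)

    def diff(atp: float) -> float:
        n = _mechanism_readout(Mechanism.NBD_ONLY, atp, base, drugs, params, settings)
        s = _mechanism_readout(Mechanism.SBD_ONLY, atp, base, drugs, params, settings)
        return n - s

    d = np.array([diff(a) for a in atp_values])
    scale = max(float(np.max(np.abs(d))), 0.0)
    readout_floor = 1e-6 * max(
        float(np.max(np.abs(d))), base.pac_ext, 1e-30
    )
    if scale <= readout_floor:
        return TransitionPoint(None, ambiguous=True)
    sign = np.sign(np.where(np.abs(d) <= readout_floor, 0.0, d))
    crossings = [
        i for i in range(len(d) - 1) if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]
    ]
    if not crossings:
        return TransitionPoint(None, ambiguous=False)
    ambiguous = len(crossings) > 1
    lo, hi = atp_values[crossings[0]], atp_values[crossings[0] + 1]
    d_lo = d[crossings[0]]
    while hi / lo - 1.0 > rel_tol:
        mid = 10 ** ((math.log10(lo) + math.log10(hi)) / 2.0)
        d_mid = diff(mid)
        if d_mid == 0.0:
            return TransitionPoint(float(mid), ambiguous)
        if (d_mid > 0) == (d_lo > 0):
            lo, d_lo = mid, d_mid
        else:
            hi = mid
    return TransitionPoint(float(math.sqrt(lo * hi)), ambiguous)


def improvement_screen(
    tki: str,
    base: Scenario,
    drugs: Mapping[str, DrugParams],
    doses: Sequence[float],
    fold: float = 10.0,
    params: KineticParameters | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> dict[str, SweepResult]:
    """Baseline plus three single-parameter-improved dose-response curves.

    ``Kd_nbd`` and ``Kd_sbd`` improvements divide the TKI's dissociation
    constant by ``fold``; ``PC`` multiplies the partition coefficient by
    ``fold`` (membrane-phase binding affinity held fixed).
    """
    doses = tuple(float(d) for d in doses)
    scn = replace(base, tki=tki, sweep=("tki_ext", doses))
    out = {"baseline": run_scenario(scn, drugs, params, settings)}
    for param in IMPROVABLE:
        improved = replace(scn, improvement=(param, float(fold)))
        out[param] = run_scenario(improved, drugs, params, settings)
    return out
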