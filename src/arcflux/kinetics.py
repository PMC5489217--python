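"""Batch-culture kinetic model: simulation, least-squares fitting, and
derived rate/yield quantities.

State variables are biomass x, substrate (xylose) S, product (ethanol) P
(all g/L) and dissolved oxygen C_L (g/L). Specific rates:

    mu  = mu_max * S / (S + Ks) * f1(t)          (Monod growth with lag)
    qP  = (alpha * mu + beta) * f2(t)            (Luedeking–Piret with delay)
    qS  = mu / Yo + m + qP / YP                  (substrate mass balance)

with logistic-in-time delay factors f = q / (q + exp(-v t)), and mass
balances dx/dt = mu x, dS/dt = -qS x, dP/dt = qP x,
dC_L/dt = kLa (C* - C_L) - qO2 x. Under oxygen limitation all transferred
oxygen is consumed, C_L stays at quasi-steady zero and qO2 = kLa C* / x.

The growth delay parameter can be written q1 = k * mu_max; q1 is the
quantity actually fitted and k is derived afterwards as q1 / mu_max.
YP is the theoretical ethanol yield from xylose and is held fixed
(0.511 g/g) during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "CultureParams",
    "CultureTrajectory",
    "delay_factor",
    "specific_rates",
    "simulate_culture",
    "fit_parameters",
    "FitResult",
    "oxygen_limited_qO2",
    "otr",
    "yield_and_productivity",
    "relative_change",
    "FITTED_PARAM_NAMES",
]

MW_O2 = 32.00  # g/mol

FITTED_PARAM_NAMES = ("mu_max", "Ks", "Yo", "m", "alpha", "beta", "q1", "q2", "v1", "v2")


@dataclass(frozen=True)
class CultureParams:
    """Kinetic parameters; defaults describe a microaerobic xylose batch.

    Units: mu_max, v1, v2, kLa in 1/h; Ks, Cstar in g/L; Yo, YP in g/g;
    m, beta in g gcell^-1 h^-1; alpha, q1, q2, k dimensionless (alpha in
    g/gcell).
    """

    mu_max: float = 0.12
    Ks: float = 1.5
    Yo: float = 0.28
    YP: float = 0.511
    m: float = 0.02
    alpha: float = 2.2
    beta: float = 0.01
    q1: float = 0.05
    q2: float = 0.05
    v1: float = 0.25
    v2: float = 0.20
    kLa: float = 15.0
    Cstar: float = 0.0075
    oxygen_limited: bool = True

    def __post_init__(self):
        for name in ("mu_max", "Ks", "Yo", "YP", "q1", "q2", "v1", "v2", "kLa", "Cstar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.m < 0 or self.beta < 0:
            raise ValueError("m and beta must be >= 0")
        if self.YP > 0.511 + 1e-12:
            raise ValueError("YP may not exceed the theoretical 0.511 g/g")

    @property
    def k(self) -> float:
        """Delay-link coefficient, derived as q1 / mu_max."""
        return self.q1 / self.mu_max


@dataclass
class CultureTrajectory:
    """Simulated (or fitted) culture state and specific-rate time series."""

    t: np.ndarray
    x: np.ndarray
    S: np.ndarray
    P: np.ndarray
    C_L: np.ndarray
    mu: np.ndarray
    qS: np.ndarray
    qP: np.ndarray
    qO2: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_h": self.t, "biomass_gL": self.x, "xylose_gL": self.S,
             "ethanol_gL": self.P, "o2_gL": self.C_L, "mu_h": self.mu,
             "qS_g_g_h": self.qS, "qP_g_g_h": self.qP, "qO2_g_g_h": self.qO2}
        )


def delay_factor(q: float, v: float, t) -> np.ndarray | float:
    """Logistic-in-time delay factor f = q / (q + e^{-v t}).

    Strictly increasing in t, from q/(q+1) at t = 0 toward 1.
    """
    if q <= 0 or v <= 0:
        raise ValueError("q and v must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = q / (q + np.exp(-v * t))
    return float(out) if out.ndim == 0 else out


def specific_rates(params: CultureParams, S, t):
    """Return (mu, qP, qS) at substrate level S and time t."""
    if params.Yo == 0 or params.YP == 0:
        raise ValueError("Yo and YP must be non-zero")
    S = np.maximum(np.asarray(S, dtype=float), 0.0)
    f1 = delay_factor(params.q1, params.v1, t)
    f2 = delay_factor(params.q2, params.v2, t)
    mu = params.mu_max * S / (S + params.Ks) * f1
    qP = (params.alpha * mu + params.beta) * f2
    qS = mu / params.Yo + params.m + qP / params.YP
    return mu, qP, qS


def oxygen_limited_qO2(kLa: float, Cstar: float, x: float) -> float:
    """Specific oxygen uptake when all transferred oxygen is consumed: kLa C*/x."""
    if x <= 0:
        raise ValueError("biomass concentration must be > 0 for a specific rate")
    return kLa * Cstar / x


def otr(kLa: float, Cstar: float) -> float:
    """Oxygen transfer rate kLa*C* in mmol O2 L^-1 h^-1 (Cstar in g/L)."""
    return kLa * Cstar / MW_O2 * 1000.0


def simulate_culture(
    params: CultureParams,
    initial_state=(0.25, 15.0, 0.0, 0.0075),
    t_span: tuple[float, float] | None = None,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CultureTrajectory:
    """Integrate the batch model with event-guarded substrate depletion.

    ``initial_state`` is (x0, S0, P0, C_L0) in g/L. Consumption terms stop
    once S reaches zero (growth and growth-associated production cease; the
    non-growth-associated term beta is also gated by substrate presence so
    that mass balances close).
    """
    x0, S0, P0, CL0 = (float(v) for v in initial_state)
    if min(x0, S0, P0, CL0) < 0:
        raise ValueError("initial concentrations must be >= 0")
    if t_eval is not None:
        t_eval = np.asarray(t_eval, dtype=float)
        t_span = (float(t_eval[0]), float(t_eval[-1]))
    elif t_span is None:
        t_span = (0.0, 48.0)

    p = params
    from math import exp

    # scalar fast path of specific_rates (the integrator calls this a few
    # hundred times per simulation and many thousand times per fit)
    def rhs(t, y):
        x, S, P, CL = y
        S = max(S, 0.0)
        x = max(x, 0.0)
        f1 = p.q1 / (p.q1 + exp(-p.v1 * t))
        f2 = p.q2 / (p.q2 + exp(-p.v2 * t))
        mu = p.mu_max * S / (S + p.Ks) * f1
        qP = (p.alpha * mu + p.beta) * f2
        qS = mu / p.Yo + p.m + qP / p.YP
        dx = mu * x
        dS = -qS * x
        dP = qP * x
        if p.oxygen_limited:
            # quasi-steady dissolved oxygen at ~0: supply == consumption
            dCL = 0.0
        else:
            dCL = p.kLa * (p.Cstar - CL)
        return [dx, dS, dP, dCL]

    # integration stops when the substrate is exhausted; the state is then
    # held constant (all consumption and production terms are
    # substrate-dependent once growth and the maintenance draw stop)
    def substrate_gone(t, y):
        return y[1]
    substrate_gone.terminal = True
    substrate_gone.direction = -1

    y0 = [x0, S0, P0, 0.0 if p.oxygen_limited else CL0]
    sol = solve_ivp(
        rhs, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol, method="LSODA",
        events=substrate_gone,
    )
    if sol.status == -1 or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"culture integration failed: {sol.message}")
    t = sol.t
    y = sol.y
    if sol.status == 1 and t_eval is not None and len(t) < len(t_eval):
        # substrate ran out: pad the remaining sample times with the final state
        y_end = sol.y[:, -1] if sol.y.shape[1] else np.array(y0)
        if sol.y_events and len(sol.y_events[0]):
            y_end = sol.y_events[0][-1]
        rest = t_eval[len(t):]
        t = np.concatenate([t, rest])
        pad = np.tile(y_end[:, None], (1, len(rest)))
        pad[1] = 0.0
        y = np.hstack([y, pad]) if y.size else pad
    x, S, P, CL = (np.maximum(y[i], 0.0) for i in range(4))
    mu, qP, qS = specific_rates(p, S, t)
    gone = S <= 1e-12
    mu = np.where(gone, 0.0, mu)
    qP = np.where(gone, 0.0, qP)
    qS = np.where(gone, 0.0, qS)
    with np.errstate(divide="ignore"):
        qO2 = np.where(x > 0, p.kLa * p.Cstar / np.maximum(x, 1e-12), 0.0)
    return CultureTrajectory(t, x, S, P, CL, mu, qS, qP, qO2)


# -- parameter estimation ---------------------------------------------------

_DEFAULT_BOUNDS = {
    "mu_max": (0.01, 1.0),
    "Ks": (0.05, 10.0),
    "Yo": (0.05, 0.9),
    "m": (0.0, 0.2),
    "alpha": (0.0, 10.0),
    "beta": (0.0, 0.2),
    "q1": (1e-3, 5.0),
    "q2": (1e-3, 5.0),
    "v1": (0.01, 2.0),
    "v2": (0.01, 2.0),
}


@dataclass
class FitResult:
    params: CultureParams
    rmse: dict[str, float]           # per-variable RMSE / observed range
    cost: float
    n_starts: int
    converged: bool
    start_costs: list[float] = field(default_factory=list)


def _simulate_fast(p: CultureParams, y0, t_eval: np.ndarray, dt: float = 0.125):
    """Fixed-step RK4 on (x, S, P); used for fitting residuals only.

    The dynamics are smooth away from substrate depletion; the depletion
    kink is handled by clamping S at zero, after which all rates vanish.
    Accuracy vs the adaptive integrator is ~1e-6 on the default problem,
    far below any data noise.
    """
    from math import exp

    mu_max, Ks, Yo, YP, m_, al, be = p.mu_max, p.Ks, p.Yo, p.YP, p.m, p.alpha, p.beta
    q1, q2, v1, v2 = p.q1, p.q2, p.v1, p.v2

    def f(t, x, S, P):
        if S <= 0.0:
            return 0.0, 0.0, 0.0
        f1 = q1 / (q1 + exp(-v1 * t))
        f2 = q2 / (q2 + exp(-v2 * t))
        mu = mu_max * S / (S + Ks) * f1
        qP = (al * mu + be) * f2
        qS = mu / Yo + m_ + qP / YP
        return mu * x, -qS * x, qP * x

    t0, t_end = float(t_eval[0]), float(t_eval[-1])
    n = max(1, int(np.ceil((t_end - t0) / dt)))
    h = (t_end - t0) / n
    ts = np.empty(n + 1)
    ys = np.empty((n + 1, 3))
    x, S, P = float(y0[0]), float(y0[1]), float(y0[2])
    ts[0] = t0
    ys[0] = (x, S, P)
    t = t0
    for i in range(n):
        k1 = f(t, x, S, P)
        k2 = f(t + h / 2, x + h / 2 * k1[0], S + h / 2 * k1[1], P + h / 2 * k1[2])
        k3 = f(t + h / 2, x + h / 2 * k2[0], S + h / 2 * k2[1], P + h / 2 * k2[2])
        k4 = f(t + h, x + h * k3[0], S + h * k3[1], P + h * k3[2])
        x += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        S += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        P += h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if S < 0.0:
            S = 0.0
        t = t0 + (i + 1) * h
        ts[i + 1] = t
        ys[i + 1] = (x, S, P)
    out = np.empty((3, len(t_eval)))
    for k in range(3):
        out[k] = np.interp(t_eval, ts, ys[:, k])
    return out


def _residuals(theta, free_names, base, data, scales):
    kw = dict(zip(free_names, theta))
    try:
        params = replace(base, **kw)
        t = data["t_h"].to_numpy()
        y0 = (data["biomass_gL"].iloc[0], data["xylose_gL"].iloc[0],
              data["ethanol_gL"].iloc[0])
        x, S, P = _simulate_fast(params, y0, t)
    except (ValueError, RuntimeError):
        return np.full(3 * len(data), 1e3)
    res = np.concatenate([
        (x - data["biomass_gL"].to_numpy()) / scales[0],
        (S - data["xylose_gL"].to_numpy()) / scales[1],
        (P - data["ethanol_gL"].to_numpy()) / scales[2],
    ])
    return res


def _initial_guess(data, base: CultureParams) -> dict[str, float]:
    """Heuristic start from the data: log-slope for mu_max, overall yields."""
    t = data["t_h"].to_numpy()
    x = np.maximum(data["biomass_gL"].to_numpy(), 1e-6)
    S = data["xylose_gL"].to_numpy()
    P = data["ethanol_gL"].to_numpy()
    grow = x > x[0] * 1.2
    if grow.sum() >= 3:
        sl = np.polyfit(t[grow][: max(3, grow.sum() // 2)],
                        np.log(x[grow][: max(3, grow.sum() // 2)]), 1)[0]
        mu_max = float(np.clip(sl * 1.3, 0.02, 0.8))
    else:
        mu_max = base.mu_max
    dS = max(S[0] - S.min(), 1e-6)
    Yo = float(np.clip((x.max() - x[0]) / dS * 2.0, 0.08, 0.8))
    alpha = float(np.clip((P.max() - P[0]) / max(x.max() - x[0], 1e-6), 0.1, 8.0))
    return {"mu_max": mu_max, "Ks": 1.0, "Yo": Yo, "m": 0.01,
            "alpha": alpha, "beta": 0.01, "q1": 0.05, "q2": 0.05,
            "v1": 0.2, "v2": 0.2}


def fit_parameters(
    data,
    fixed: dict[str, float] | None = None,
    init_guess: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    base_params: CultureParams | None = None,
) -> FitResult:
    """Least-squares fit of the kinetic model to a culture time series.

    ``data`` is a DataFrame with columns t_h, biomass_gL, xylose_gL,
    ethanol_gL. The ten parameters mu_max, Ks, Yo, m, alpha, beta, q1, q2,
    v1, v2 are free unless listed in ``fixed``; YP stays at its theoretical
    value. Residuals are normalised per variable by the observed range.
    Multi-start: the first start is a data-driven heuristic guess, the rest
    are seeded log-uniform draws within bounds; the best converged start is
    returned.
    """
    fixed = dict(fixed or {})
    base = base_params or CultureParams()
    if fixed:
        base = replace(base, **fixed)
    free_names = [p for p in FITTED_PARAM_NAMES if p not in fixed]
    if len(data) < max(1, len(free_names)):
        raise ValueError(
            f"need at least {len(free_names)} data points for {len(free_names)} free parameters"
        )
    scales = [
        max(np.ptp(data[c].to_numpy()), 1e-6)
        for c in ("biomass_gL", "xylose_gL", "ethanol_gL")
    ]
    if not free_names:
        res = _residuals([], free_names, base, data, scales)
        n = len(data)
        rmse = {
            v: float(np.sqrt(np.mean(res[i * n:(i + 1) * n] ** 2)))
            for i, v in enumerate(("biomass", "xylose", "ethanol"))
        }
        return FitResult(base, rmse, float(0.5 * np.sum(res ** 2)), 0, True)

    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[p][0] for p in free_names])
    hi = np.array([bnds[p][1] for p in free_names])

    guess = _initial_guess(data, base)
    if init_guess:
        guess.update(init_guess)
    x0_first = np.clip([guess[p] for p in free_names], lo, hi)

    rng = np.random.default_rng(seed)
    starts = [x0_first]
    for _ in range(max(0, n_starts - 1)):
        u = rng.uniform(size=len(free_names))
        lo_pos = np.maximum(lo, 1e-6)
        draw = np.exp(np.log(lo_pos) + u * (np.log(hi) - np.log(lo_pos)))
        starts.append(np.clip(draw, lo, hi))

    best = None
    start_costs = []
    for x0 in starts:
        try:
            out = least_squares(
                _residuals, x0, bounds=(lo, hi),
                args=(free_names, base, data, scales),
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400,
            )
        except Exception:
            start_costs.append(np.inf)
            continue
        start_costs.append(out.cost)
        if best is None or out.cost < best.cost:
            best = out
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed to converge; start costs: {start_costs}"
        )
    params = replace(base, **dict(zip(free_names, best.x)))
    res = best.fun
    n = len(data)
    rmse = {
        v: float(np.sqrt(np.mean(res[i * n:(i + 1) * n] ** 2)))
        for i, v in enumerate(("biomass", "xylose", "ethanol"))
    }
    return FitResult(params, rmse, float(best.cost), len(starts),
                     bool(best.success), start_costs)


# -- yields and productivities ----------------------------------------------

def yield_and_productivity(data) -> tuple[float, float]:
    """Overall ethanol yield (g/g consumed xylose) and volumetric productivity.

    Accepts a culture DataFrame (t_h, xylose_gL, ethanol_gL) or a
    :class:`CultureTrajectory`. Productivity is dP over the production
    interval (first to last time where P increases).
    """
    if isinstance(data, CultureTrajectory):
        t, S, P = data.t, data.S, data.P
    else:
        t = data["t_h"].to_numpy()
        S = data["xylose_gL"].to_numpy()
        P = data["ethanol_gL"].to_numpy()
    dS = S[0] - S[-1]
    dP = P[-1] - P[0]
    if dS <= 0:
        raise ValueError("no xylose consumed; yield undefined")
    if dP <= 0:
        return 0.0, 0.0
    Y = dP / dS
    produced = np.where(P > P[0] + 1e-9)[0]
    t_end = t[produced[-1]] if len(produced) else t[-1]
    t_start = t[0]
    Q = dP / max(t_end - t_start, 1e-9)
    return float(Y), float(Q)


def relative_change(a: float, b: float) -> float:
    """Percent change of a relative to b: 100*(a-b)/b."""
    if b == 0:
        raise ValueError("reference value is zero")
    return 100.0 * (a - b) / b
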