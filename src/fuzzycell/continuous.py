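"""Continuous dynamics: fuzzy rules -> sigmoid drive -> ODE system.

Each non-input node k evolves as

    dq_k/dt = mu[w_k(q_1, ..., q_n)] - d_k q_k ,

where w_k is the node's rule evaluated under the fuzzy algebra
(product / probabilistic sum / complement), mu is the logistic membership
function

    mu[w] = 1 / (1 + exp(-beta (w - w_thr))) ,

d_k the node's decay rate, and input nodes follow prescribed time
functions.  Steady states satisfy q_k = mu[w_k(q*)] / d_k.

A node with decay d_k < 1 can sustain levels above 1 (its steady level is
mu/d_k); levels are clamped to [0, 1] *before* entering rule expressions,
i.e. expression above full saturation carries no extra regulatory weight.
Piecewise-constant inputs are handled by splitting the integration at each
discontinuity time, with the step value itself left-closed (the level at
t = tau is still the pre-detachment avidity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .rules import And, Expr, NetworkModel, Not, Or, RuleError, Var

__all__ = [
    "MembershipParams",
    "membership",
    "Trajectory",
    "SteadyState",
    "SimulationError",
    "ConvergenceError",
    "compile_system",
    "rhs",
    "simulate",
    "find_steady_state",
]


class SimulationError(RuntimeError):
    """Integrator failure (with node/time context where available)."""


class ConvergenceError(RuntimeError):
    """No steady state found (e.g. the regime is oscillatory)."""


@dataclass(frozen=True)
class MembershipParams:
    """Sigmoid gain ``beta`` and activation threshold ``w_thr``."""

    beta: float = 5.0
    w_thr: float = 0.5

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.w_thr < 1.0):
            raise ValueError("w_thr must lie in (0, 1)")


def membership(w, params: MembershipParams | None = None, *,
               beta: float | None = None, w_thr: float | None = None):
    """Logistic membership mu[w]; strictly increasing, mu(w_thr) = 1/2."""
    if params is None:
        params = MembershipParams(beta if beta is not None else 5.0,
                                  w_thr if w_thr is not None else 0.5)
    return 1.0 / (1.0 + np.exp(-params.beta * (np.asarray(w, float) - params.w_thr)))


# ---------------------------------------------------------------------------
# Rule compilation
# ---------------------------------------------------------------------------


def _compile_fuzzy(expr: Expr, index: Mapping[str, int]) -> Callable:
    """Compile an expression tree to a closure over a level array."""
    if isinstance(expr, Var):
        i = index[expr.name]
        return lambda y, i=i: y[i]
    if isinstance(expr, Not):
        c = _compile_fuzzy(expr.child, index)
        return lambda y, c=c: 1.0 - c(y)
    if isinstance(expr, And):
        cs = [_compile_fuzzy(c, index) for c in expr.children]
        def f_and(y, cs=cs):
            out = 1.0
            for c in cs:
                out *= c(y)
            return out
        return f_and
    if isinstance(expr, Or):
        cs = [_compile_fuzzy(c, index) for c in expr.children]
        def f_or(y, cs=cs):
            out = 0.0
            for c in cs:
                v = c(y)
                out = out + v - out * v
            return out
        return f_or
    raise TypeError(f"cannot compile {type(expr).__name__}")


@dataclass
class _System:
    model: NetworkModel
    free: list[str]
    inputs: list[str]
    index: dict[str, int]
    w_funcs: list[Callable]
    decay: np.ndarray
    params: MembershipParams

    def drives(self, levels: np.ndarray) -> np.ndarray:
        """w_k for every free node, given the combined clamped level array."""
        return np.array([f(levels) for f in self.w_funcs])


def compile_system(model: NetworkModel,
                   params: MembershipParams | None = None) -> _System:
    free = model.free_names
    inputs = model.input_names
    index = {name: i for i, name in enumerate(free + inputs)}
    w_funcs = []
    for name in free:
        rule = model.nodes[name].rule
        if rule is None:
            w_funcs.append(lambda y: 0.0)
        else:
            w_funcs.append(_compile_fuzzy(rule, index))
    decay = np.array([model.nodes[n].decay for n in free])
    if params is None:
        params = MembershipParams(model.beta, model.w_thr)
    return _System(model, free, inputs, index, w_funcs, decay, params)


def _input_callables(system: _System, inputs) -> list[Callable[[float], float]]:
    funcs = []
    table = dict(inputs or {})
    unknown = set(table) - set(system.inputs)
    if unknown:
        raise RuleError(f"unknown input node(s): {sorted(unknown)}")
    for name in system.inputs:
        u = table.get(name, 0.0)
        if callable(u):
            funcs.append(u)
        else:
            funcs.append(lambda t, v=float(u): v)
    return funcs


def rhs(model: NetworkModel, state: Mapping[str, float], t: float = 0.0,
        inputs=None, params: MembershipParams | None = None) -> dict[str, float]:
    """Per-node derivative mu[w_k] - d_k q_k at one state (reference path).

    ``state`` maps free-node names to levels; ``inputs`` maps input names to
    constants or time functions.  Input nodes are driven externally and do
    not appear in the returned derivative map.
    """
    system = compile_system(model, params)
    x = np.array([state[n] for n in system.free], float)
    if np.any(x < 0):
        raise ValueError("levels must be non-negative")
    ivals = [f(t) for f in _input_callables(system, inputs)]
    levels = np.concatenate([np.clip(x, 0.0, 1.0), ivals])
    w = system.drives(levels)
    dq = membership(w, system.params) - system.decay * x
    return dict(zip(system.free, dq))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time grid plus continuous per-node levels (inputs included)."""

    times: np.ndarray
    levels: pd.DataFrame          # one column per node, aligned to times
    config: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.levels[name].to_numpy()

    def final(self, name: str) -> float:
        return float(self.levels[name].iloc[-1])

    def peak(self, name: str) -> float:
        return float(self.levels[name].max())

    def to_wide_tsv(self, path, display: bool = True) -> None:
        df = self.levels.copy()
        if display and "display_names" in self.config:
            df = df.rename(columns=self.config["display_names"])
        df.insert(0, "time", self.times)
        df.to_csv(path, sep="\t", index=False)

    def to_long_tsv(self, path, display: bool = True) -> None:
        df = self.levels.copy()
        if display and "display_names" in self.config:
            df = df.rename(columns=self.config["display_names"])
        df.insert(0, "time", self.times)
        long = df.melt(id_vars="time", var_name="node", value_name="level")
        long.to_csv(path, sep="\t", index=False)


@dataclass
class SteadyState:
    """A root of mu[w_k(q*)] = d_k q_k, with the achieved residual."""

    levels: dict[str, float]
    residual: float


def simulate(
    model: NetworkModel,
    inputs=None,
    initial: Mapping[str, float] | None = None,
    horizon: float = 60.0,
    n_points: int = 500,
    params: MembershipParams | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    discontinuities: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the fuzzy-ODE system under time-dependent inputs.

    ``inputs`` maps input-node names to constants or callables ``u(t)``
    (an :class:`~fuzzycell.stimulation.InputSet` carries its discontinuity
    times along; otherwise pass ``discontinuities`` explicitly for
    piecewise inputs).  Missing inputs are held at 0.  Initial levels
    default to the per-node ``initial`` attribute.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    system = compile_system(model, params)
    ufuncs = _input_callables(system, inputs)
    if discontinuities is None:
        discontinuities = tuple(getattr(inputs, "discontinuities", ()))
    breaks = sorted({float(tb) for tb in discontinuities if 0.0 < tb < horizon})
    edges = [0.0] + breaks + [float(horizon)]

    x0 = np.array(
        [
            float(initial[n]) if initial and n in initial else model.nodes[n].initial
            for n in system.free
        ]
    )
    if np.any(x0 < 0):
        raise ValueError("initial levels must be non-negative")

    n_free = len(system.free)
    levels_buf = np.empty(n_free + len(system.inputs))

    grid = np.linspace(0.0, float(horizon), int(n_points))
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []

    x = x0
    for lo, hi in zip(edges[:-1], edges[1:]):
        # inputs are evaluated just inside the segment so that the value at a
        # discontinuity time itself stays left-closed
        t_in = np.nextafter(lo, math.inf)

        def seg_rhs(t, xx):
            te = t if t > lo else t_in
            levels_buf[:n_free] = np.clip(xx, 0.0, 1.0)
            for j, f in enumerate(ufuncs):
                levels_buf[n_free + j] = f(te)
            w = system.drives(levels_buf)
            return membership(w, system.params) - system.decay * xx

        if lo == 0.0:
            seg_grid = grid[(grid >= lo) & (grid <= hi)]
        else:
            seg_grid = grid[(grid > lo) & (grid <= hi)]
        t_eval = np.unique(np.concatenate([[lo], seg_grid, [hi]]))
        sol = solve_ivp(
            seg_rhs, (lo, hi), x, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{lo}, {hi}]: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"non-finite levels on [{lo}, {hi}]")
        keep = np.isin(sol.t, seg_grid)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
        x = sol.y[:, -1]

    times = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=1)
    # input columns on the same grid (left-closed at the breaks)
    data = {name: states[i] for i, name in enumerate(system.free)}
    for j, name in enumerate(system.inputs):
        f = ufuncs[j]
        data[name] = np.array([f(t) for t in times])
    df = pd.DataFrame(data, columns=system.free + system.inputs)
    config = {
        "beta": system.params.beta,
        "w_thr": system.params.w_thr,
        "horizon": float(horizon),
        "n_points": int(n_points),
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "decay": {n: model.nodes[n].decay for n in system.free
                  if model.nodes[n].decay != 1.0},
        "discontinuities": breaks,
        "display_names": dict(model.display_names),
    }
    return Trajectory(times=times, levels=df, config=config)


def find_steady_state(
    model: NetworkModel,
    inputs: Mapping[str, float] | None = None,
    start: Mapping[str, float] | None = None,
    params: MembershipParams | None = None,
    horizon: float = 200.0,
    tol: float = 1e-6,
) -> SteadyState:
    """Steady state under constant inputs: integrate, then polish by rooting.

    Raises :class:`ConvergenceError` when the long-horizon endpoint is not
    settling (an oscillatory regime), distinctly from integrator failure.
    """
    const = {}
    for name, u in (inputs or {}).items():
        if callable(u):
            raise ValueError("find_steady_state requires constant inputs")
        const[name] = float(u)
    system = compile_system(model, params)
    traj = simulate(model, const, initial=start, horizon=horizon,
                    n_points=200, params=system.params)
    end = traj.levels[system.free].to_numpy()
    drift = np.abs(end[-1] - end[-20]).max()

    uvals = np.array([const.get(n, 0.0) for n in system.inputs])

    def F(x):
        levels = np.concatenate([np.clip(x, 0.0, 1.0), uvals])
        w = system.drives(levels)
        return membership(w, system.params) - system.decay * x

    sol = root(F, end[-1], method="hybr", tol=1e-12)
    resid = float(np.abs(F(sol.x)).max())
    if not sol.success or resid > tol or drift > 1e-3:
        if drift > 1e-3:
            raise ConvergenceError(
                f"no steady state: endpoint still drifting (|dq| ~ {drift:.2e}); "
                "the regime may be oscillatory"
            )
        raise ConvergenceError(f"root polishing failed (residual {resid:.2e})")
    return SteadyState(levels=dict(zip(system.free, map(float, sol.x))),
                       residual=resid)
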