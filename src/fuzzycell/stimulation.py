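"""Time-dependent inputs: step-function avidity and constant cytokine clamps.

Antigen presentation (MHC-antigen -> TCR) and co-stimulation (CD80/86 ->
CD28) are modelled as step functions: an engagement of avidity A that drops
by a detachment magnitude D once the stimulation time tau has elapsed,

    u(t) = A - D * H(t - tau),    H = Heaviside step,

with the left-closed convention u(tau) = A (full avidity is retained at the
stimulation time itself and drops immediately after).  Exogenous cytokines
carry no temporal structure and are clamped to constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .rules import NetworkModel, RuleError

__all__ = ["StepInput", "avidity_at", "InputSet", "build_input_set"]


@dataclass(frozen=True)
class StepInput:
    """Step-function engagement profile for one input node.

    ``avidity`` (A) is the initial engagement strength in [0, 1];
    ``detach`` (D) the drop at ``tau`` (defaults to A: full detachment);
    ``node`` names the driven input.
    """

    node: str
    avidity: float = 1.0
    tau: float = 15.0
    detach: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.avidity <= 1.0):
            raise ValueError("avidity must lie in [0, 1]")
        d = self.avidity if self.detach is None else self.detach
        if not (0.0 <= d <= self.avidity):
            raise ValueError("detachment must lie in [0, avidity]")
        if self.tau <= 0:
            raise ValueError("stimulation time tau must be positive")
        object.__setattr__(self, "detach", d)

    def __call__(self, t: float) -> float:
        return avidity_at(self, t)


def avidity_at(step: StepInput, t: float) -> float:
    """Engagement level at time t: A for t <= tau, A - D afterwards."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return step.avidity if t <= step.tau else step.avidity - step.detach


class InputSet(dict):
    """Input-node -> time-function map that remembers its discontinuities."""

    def __init__(self, funcs: Mapping[str, Callable[[float], float]],
                 discontinuities=()):
        super().__init__(funcs)
        self.discontinuities = tuple(sorted(set(discontinuities)))


def build_input_set(
    model: NetworkModel,
    steps: Mapping[str, StepInput] | list[StepInput] | None = None,
    constants: Mapping[str, float] | None = None,
) -> InputSet:
    """Assemble the full input map for a simulation.

    ``steps`` drives nodes with step-function engagement profiles;
    ``constants`` clamps nodes (e.g. exogenous cytokines) to fixed levels.
    Every referenced node must be a declared input of *model*; unreferenced
    inputs default to constant 0.  The returned functions are pure.
    """
    declared = set(model.input_names)
    funcs: dict[str, Callable[[float], float]] = {}
    breaks: list[float] = []

    if steps is not None:
        step_list = list(steps.values()) if isinstance(steps, Mapping) else list(steps)
        for step in step_list:
            if step.node not in declared:
                raise RuleError(f"unknown input node {step.node!r}")
            if step.node in funcs:
                raise RuleError(f"input {step.node!r} driven twice")
            funcs[step.node] = step
            if step.detach:
                breaks.append(step.tau)

    for name, level in (constants or {}).items():
        if name not in declared:
            raise RuleError(f"unknown input node {name!r}")
        if name in funcs:
            raise RuleError(f"input {name!r} driven twice")
        level = float(level)
        if not (0.0 <= level <= 1.0):
            raise ValueError(f"constant input {name!r} outside [0, 1]")
        funcs[name] = (lambda t, v=level: v)

    for name in declared - set(funcs):
        funcs[name] = (lambda t: 0.0)

    return InputSet(funcs, breaks)
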