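"""Synchronous Boolean dynamics, attractor search, robustness perturbations.

States are assignments of {0, 1} to every node.  Non-input nodes update
simultaneously from the time-t state; input nodes stay clamped.  Attractors
(fixed points and cycles) are found either by exhaustive enumeration of the
free-node state space (feasible up to a configurable bit cap) or from
seeded random starts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .rules import Expr, NetworkModel, RuleError

__all__ = [
    "Attractor",
    "step_synchronous",
    "find_attractors",
    "walk_to_attractor",
    "robustness_bitflip",
    "rule_bitflip_report",
    "StatePerturbationReport",
    "RulePerturbationReport",
]


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------


def step_synchronous(model: NetworkModel, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update: every non-input node recomputed from *state*."""
    nxt: dict[str, int] = {}
    for name, node in model.nodes.items():
        if node.is_input:
            if name not in state:
                raise RuleError(f"input {name!r} missing from state")
            nxt[name] = int(state[name])
        elif node.rule is None:
            nxt[name] = 0
        else:
            nxt[name] = node.rule.eval_boolean(state)
    return nxt


class _Stepper:
    """Bitmask-encoded synchronous stepping over the free nodes."""

    def __init__(self, model: NetworkModel, inputs: Mapping[str, int]):
        self.model = model
        self.free = model.free_names
        self.n = len(self.free)
        unknown = set(inputs) - set(model.input_names)
        if unknown:
            raise RuleError(f"unknown input node(s): {sorted(unknown)}")
        self.inputs = {name: int(inputs.get(name, 0)) for name in model.input_names}
        for v in self.inputs.values():
            if v not in (0, 1):
                raise RuleError("clamped inputs must be 0 or 1")
        self._rules = [model.nodes[name].rule for name in self.free]

    def decode(self, code: int) -> dict[str, int]:
        state = dict(self.inputs)
        for i, name in enumerate(self.free):
            state[name] = (code >> i) & 1
        return state

    def encode(self, state: Mapping[str, int]) -> int:
        code = 0
        for i, name in enumerate(self.free):
            if state[name]:
                code |= 1 << i
        return code

    def step(self, code: int) -> int:
        state = self.decode(code)
        out = 0
        for i, rule in enumerate(self._rules):
            if rule is not None and rule.eval_boolean(state):
                out |= 1 << i
        return out

    def bits(self, code: int) -> tuple[int, ...]:
        return tuple((code >> i) & 1 for i in range(self.n))


@dataclass(frozen=True)
class Attractor:
    """A fixed point (cycle length 1) or limit cycle of the synchronous map.

    ``states`` holds the cycle in canonical rotation (starting from the
    lexicographically smallest bit tuple, in declared free-node order).
    ``basin`` is an exact count under exhaustive search, an observed count
    of sampled starts otherwise.
    """

    states: tuple[tuple[int, ...], ...]
    node_names: tuple[str, ...]
    inputs: tuple[tuple[str, int], ...]
    basin: int = 0
    exhaustive: bool = False

    @property
    def period(self) -> int:
        return len(self.states)

    def as_dicts(self) -> list[dict[str, int]]:
        base = dict(self.inputs)
        return [
            {**base, **dict(zip(self.node_names, bits))} for bits in self.states
        ]

    def bitstrings(self) -> list[str]:
        return ["".join(str(b) for b in bits) for bits in self.states]


def _canonical_cycle(cycle: list[int], stepper: _Stepper) -> tuple[tuple[int, ...], ...]:
    tuples = [stepper.bits(c) for c in cycle]
    k = min(range(len(tuples)), key=lambda i: tuples[i])
    return tuple(tuples[k:] + tuples[:k])


def walk_to_attractor(
    model: NetworkModel,
    start: Mapping[str, int],
    inputs: Mapping[str, int] | None = None,
) -> tuple[list[dict[str, int]], list[dict[str, int]]]:
    """Iterate the synchronous map from *start* until a state repeats.

    Returns ``(transient, cycle)`` as lists of full state dicts; the
    transient excludes the cycle states.
    """
    inputs = dict(inputs or {})
    for name in model.input_names:
        inputs.setdefault(name, int(start.get(name, 0)))
    st = _Stepper(model, inputs)
    code = st.encode(start)
    seen: dict[int, int] = {}
    path: list[int] = []
    while code not in seen:
        seen[code] = len(path)
        path.append(code)
        code = st.step(code)
    k = seen[code]
    transient = [st.decode(c) for c in path[:k]]
    cycle = [st.decode(c) for c in path[k:]]
    return transient, cycle


# ---------------------------------------------------------------------------
# Attractor search
# ---------------------------------------------------------------------------


def find_attractors(
    model: NetworkModel,
    inputs: Mapping[str, int] | None = None,
    starts: str | int = "all",
    seed: int = 0,
    cap: int = 20,
) -> list[Attractor]:
    """Attractors of the synchronous dynamics under clamped *inputs*.

    ``starts="all"`` enumerates the full free-node state space (refused
    above ``cap`` free bits); an integer asks for that many seeded random
    starts, with basins estimated by start counts.
    """
    st = _Stepper(model, inputs or {})
    n = st.n
    input_items = tuple(sorted(st.inputs.items()))
    names = tuple(st.free)

    attractor_of: dict[int, int] = {}   # state code -> attractor index
    cycles: list[list[int]] = []
    basins: list[int] = []

    if starts == "all":
        if n > cap:
            raise ValueError(
                f"exhaustive search over {n} free nodes exceeds the cap ({cap}); "
                "use sampled starts"
            )
        start_codes: Iterable[int] = range(1 << n)
    else:
        n_starts = int(starts)
        if n_starts < 1:
            raise ValueError("number of sampled starts must be >= 1")
        rng = random.Random(seed)
        start_codes = (rng.getrandbits(n) for _ in range(n_starts))

    for code in start_codes:
        path: list[int] = []
        c = code
        while c not in attractor_of:
            path.append(c)
            attractor_of[c] = -1  # provisional marker for the current walk
            c = st.step(c)
        idx = attractor_of[c]
        if idx == -1:
            # closed a new cycle inside the current walk
            k = path.index(c)
            cycle = path[k:]
            idx = len(cycles)
            cycles.append(cycle)
            basins.append(0)
        for p in path:
            attractor_of[p] = idx
        basins[idx] += 1  # count this start

    # For exhaustive search every state is a start exactly once, so the
    # start count equals the exact basin size.
    out = []
    for idx, cycle in enumerate(cycles):
        out.append(
            Attractor(
                states=_canonical_cycle(cycle, st),
                node_names=names,
                inputs=input_items,
                basin=basins[idx],
                exhaustive=(starts == "all"),
            )
        )
    # verify by re-stepping
    for att in out:
        for bits, nxt in zip(att.states, att.states[1:] + att.states[:1]):
            state = dict(att.inputs)
            state.update(zip(names, bits))
            stepped = st.bits(st.step(st.encode(state)))
            if stepped != nxt:
                raise AssertionError("attractor failed re-stepping verification")
    out.sort(key=lambda a: (-a.basin, a.states))
    return out


# ---------------------------------------------------------------------------
# Robustness perturbations
# ---------------------------------------------------------------------------


@dataclass
class StatePerturbationReport:
    """Noise-in-initial-states robustness summary."""

    n_trials: int
    return_fraction: float
    mean_transient_hamming: float
    n_flips: int
    seed: int


@dataclass
class RulePerturbationReport:
    """Truth-table bit-flip robustness summary."""

    n_trials: int
    preserve_fraction: float
    seed: int
    flipped: list[tuple[str, int]] = field(default_factory=list)


def _attractor_key(att: Attractor) -> tuple:
    return att.states


def robustness_bitflip(
    model: NetworkModel,
    attractor_or_state,
    n_flips: int = 1,
    seed: int = 0,
    inputs: Mapping[str, int] | None = None,
    max_trials: int = 2000,
) -> StatePerturbationReport:
    """Perturb states of an attractor by flipping bits; measure recovery.

    Every state of the attractor is perturbed (all single-bit flips when
    ``n_flips == 1`` and the count permits, seeded random flip sets
    otherwise).  Reports the fraction of perturbed states that relax back
    to the original attractor and the mean Hamming distance to the
    attractor along the transients.
    """
    if n_flips < 1:
        raise ValueError("n_flips must be >= 1")
    if isinstance(attractor_or_state, Attractor):
        att = attractor_or_state
        base_states = att.as_dicts()
        clamp = dict(att.inputs)
        target = set(att.states)
        names = list(att.node_names)
    else:
        state = dict(attractor_or_state)
        clamp = dict(inputs or {})
        for name in model.input_names:
            clamp.setdefault(name, int(state.get(name, 0)))
        _, cycle = walk_to_attractor(model, state, clamp)
        st0 = _Stepper(model, clamp)
        codes = [st0.encode(s) for s in cycle]
        target = set(_canonical_cycle(codes, st0))
        names = st0.free
        base_states = cycle
    st = _Stepper(model, clamp)
    n = st.n
    rng = random.Random(seed)

    trials: list[tuple[int, tuple[int, ...]]] = []
    base_codes = [st.encode(s) for s in base_states]
    if n_flips == 1 and len(base_codes) * n <= max_trials:
        for code in base_codes:
            for i in range(n):
                trials.append((code, (i,)))
    else:
        for _ in range(max_trials):
            code = rng.choice(base_codes)
            flips = tuple(rng.sample(range(n), min(n_flips, n)))
            trials.append((code, flips))

    returned = 0
    hamming_sum = 0.0
    hamming_n = 0
    for code, flips in trials:
        pert = code
        for i in flips:
            pert ^= 1 << i
        # walk to attractor, tracking distance to the target cycle
        seen: dict[int, int] = {}
        path = []
        c = pert
        while c not in seen:
            seen[c] = len(path)
            path.append(c)
            c = st.step(c)
        k = seen[c]
        cycle = path[k:]
        canon = _canonical_cycle(cycle, st)
        if set(canon) == target:
            returned += 1
        target_codes = [st.encode({**dict(st.inputs), **dict(zip(names, bits))})
                        for bits in target]
        for p in path[:k]:
            d = min(bin(p ^ tc).count("1") for tc in target_codes)
            hamming_sum += d
            hamming_n += 1
    return StatePerturbationReport(
        n_trials=len(trials),
        return_fraction=returned / len(trials) if trials else 1.0,
        mean_transient_hamming=hamming_sum / hamming_n if hamming_n else 0.0,
        n_flips=n_flips,
        seed=seed,
    )


def rule_bitflip_report(
    model: NetworkModel,
    inputs: Mapping[str, int] | None = None,
    seed: int = 0,
    max_trials: int = 500,
    starts: str | int = "all",
    cap: int = 20,
) -> RulePerturbationReport:
    """Flip single outputs of rule truth tables; check attractor-set stability.

    Each trial overrides one row of one node's truth table and recomputes
    the attractor set under the same clamped inputs; the report gives the
    fraction of flips that leave the attractor set unchanged.
    """
    baseline = {
        _attractor_key(a) for a in find_attractors(model, inputs, starts=starts,
                                                   seed=seed, cap=cap)
    }
    rng = random.Random(seed)

    # enumerate (node, truth-table row) pairs
    cells: list[tuple[str, tuple[str, ...], int]] = []
    for name in model.free_names:
        rule = model.nodes[name].rule
        if rule is None:
            continue
        vs = tuple(sorted(rule.variables()))
        for row in range(1 << len(vs)):
            cells.append((name, vs, row))
    if len(cells) > max_trials:
        cells = rng.sample(cells, max_trials)

    preserved = 0
    flipped_record: list[tuple[str, int]] = []
    for name, vs, row in cells:
        perturbed = model.copy()
        perturbed.nodes[name].rule = _FlippedRule(model.nodes[name].rule, vs, row)
        atts = {
            _attractor_key(a)
            for a in find_attractors(perturbed, inputs, starts=starts,
                                     seed=seed, cap=cap)
        }
        if atts == baseline:
            preserved += 1
        else:
            flipped_record.append((name, row))
    return RulePerturbationReport(
        n_trials=len(cells),
        preserve_fraction=preserved / len(cells) if cells else 1.0,
        seed=seed,
        flipped=flipped_record,
    )


class _FlippedRule(Expr):
    """A rule with one truth-table output inverted (internal helper)."""

    def __init__(self, base: Expr, variables: tuple[str, ...], row: int):
        self.base = base
        self.vars = variables
        self.row = row

    def eval_boolean(self, state):
        idx = 0
        for i, v in enumerate(self.vars):
            if state[v]:
                idx |= 1 << i
        val = self.base.eval_boolean(state)
        return 1 - val if idx == self.row else val

    def eval_fuzzy(self, state):  # pragma: no cover - not used for rule flips
        raise NotImplementedError("flipped rules are Boolean-only")

    def _vars(self):
        yield from self.vars

    def signed_vars(self, negated=False):  # pragma: no cover
        for v in self.vars:
            yield (v, negated)

    def to_text(self, parent_prec=0):  # pragma: no cover
        return f"flip({self.base.to_text()}, row={self.row})"

    def _key(self):
        return (self.base, self.vars, self.row)
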