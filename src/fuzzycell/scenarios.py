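"""Computational experiments on the T CD4 network.

Covers regime classification of trajectories (no activation / sustained /
regulated), the named stimulation scenarios of the activation study
(optimal engagement, CTLA-4 checkpoint, anergy under incomplete
stimulation, Th1/Th2/Th17/Treg differentiation), metabolic-polarity
summaries (OXPHOS vs glycolysis), and the (tau_stim, d_CTLA4) phase
diagram with bisection-refined regime boundaries.

Classification operates on a composite activation signal: the pointwise
*minimum* over a readout set (default NFAT, NFkB, AP-1 and the IL-2 gene)
— the activation program counts as engaged only while all of its outputs
are expressed.  A trajectory is *sustained* when the composite stays above
the threshold through the tail window, *regulated* when it peaked above
threshold but has fallen below it by the tail, and *no activation* when it
never crossed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assets import load_tcd4
from .continuous import Trajectory, simulate
from .rules import NetworkModel
from .stimulation import StepInput, build_input_set

__all__ = [
    "RegimeLabel",
    "MetabolicSummary",
    "PhaseDiagram",
    "classify_regime",
    "metabolic_summary",
    "run_scenario",
    "scan_phase_diagram",
    "SCENARIOS",
    "DEFAULT_READOUTS",
]

DEFAULT_READOUTS = ("NFAT", "NFKB", "AP1", "IL2G")


@dataclass
class MetabolicSummary:
    """OXPHOS/glycolysis polarity of one trajectory."""

    polarity: str                 # oxphos_dominant | glycolysis_dominant | baseline
    oxphos_peak_time: float
    oxphos_peak: float
    crossing_time: float | None   # first time glycolysis exceeds OXPHOS
    final_oxphos: float
    final_glycolysis: float


@dataclass
class RegimeLabel:
    """Categorical activation outcome plus readout and metabolic summaries."""

    category: str                 # no_activation | sustained | regulated
    peak: float
    tail_mean: float
    readout_peaks: dict[str, float] = field(default_factory=dict)
    readout_finals: dict[str, float] = field(default_factory=dict)
    metabolic: MetabolicSummary | None = None


def classify_regime(
    traj: Trajectory,
    readouts: Sequence[str] = DEFAULT_READOUTS,
    theta: float = 0.5,
    tail_fraction: float = 0.2,
    aggregate: str = "min",
    min_dwell: float = 1.0,
) -> RegimeLabel:
    """Label a trajectory as no_activation / sustained / regulated.

    The composite activation signal aggregates the readout levels pointwise
    (``min`` by default; ``mean`` and ``max`` are available).  With peak =
    max_t composite and tail = mean of the composite over the final
    ``tail_fraction`` of the horizon: no_activation when peak < theta,
    sustained when tail >= theta, regulated otherwise.

    Crossing the threshold counts as activation only when the composite
    stays above theta for a cumulative time of at least ``min_dwell``
    (default: one characteristic expression time, 1/d = 1): a trajectory
    that merely grazes the threshold commits nothing downstream and is
    still *no activation*.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    missing = [r for r in readouts if r not in traj.levels.columns]
    if missing:
        raise KeyError(f"readout node(s) not in trajectory: {missing}")
    sig = traj.levels[list(readouts)].to_numpy()
    if aggregate == "min":
        composite = sig.min(axis=1)
    elif aggregate == "mean":
        composite = sig.mean(axis=1)
    elif aggregate == "max":
        composite = sig.max(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    horizon = traj.times[-1] - traj.times[0]
    tail_start = traj.times[-1] - tail_fraction * horizon
    tail_mask = traj.times >= tail_start
    if not tail_mask.any():
        raise ValueError("horizon shorter than the tail window")
    peak = float(composite.max())
    tail_mean = float(composite[tail_mask].mean())
    dwell = float(np.trapezoid((composite >= theta).astype(float), traj.times))

    if peak < theta or dwell < min_dwell:
        category = "no_activation"
    elif tail_mean >= theta:
        category = "sustained"
    else:
        category = "regulated"
    return RegimeLabel(
        category=category,
        peak=peak,
        tail_mean=tail_mean,
        readout_peaks={r: float(traj.levels[r].max()) for r in readouts},
        readout_finals={r: float(traj.levels[r].iloc[-1]) for r in readouts},
    )


def metabolic_summary(traj: Trajectory, theta_met: float = 0.2) -> MetabolicSummary:
    """Polarity report: OXPHOS peak, glycolysis crossing, end-state dominance.

    The end state is ``baseline`` when both OXPHOS and glycolysis finish
    below ``theta_met``, otherwise whichever is larger dominates.
    """
    ox = traj["OXPHOS"]
    gly = traj["GLYCOLYSIS"]
    t = traj.times
    i_peak = int(np.argmax(ox))
    above = np.nonzero(gly > ox)[0]
    crossing = float(t[above[0]]) if above.size else None
    fo, fg = float(ox[-1]), float(gly[-1])
    if fo < theta_met and fg < theta_met:
        polarity = "baseline"
    elif fg > fo:
        polarity = "glycolysis_dominant"
    else:
        polarity = "oxphos_dominant"
    return MetabolicSummary(
        polarity=polarity,
        oxphos_peak_time=float(t[i_peak]),
        oxphos_peak=float(ox[i_peak]),
        crossing_time=crossing,
        final_oxphos=fo,
        final_glycolysis=fg,
    )


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

#: scenario presets: step avidities, stimulation time, CTLA-4 decay rate and
#: exogenous cytokine context.  Differentiation runs use optimal engagement
#: with fast CTLA-4 turnover (low-level checkpoint activity) plus the
#: lineage-inducing cytokines.
SCENARIOS: dict[str, dict] = {
    "optimal_sustained": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=5.0, cytokines={}),
    "checkpoint": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=0.5, cytokines={}),
    "anergy_weak_costim": dict(a_mhc=1.0, a_cd=0.5, tau=15.0, d_ctla4=1.0, cytokines={}),
    "anergy_weak_tcr": dict(a_mhc=0.5, a_cd=1.0, tau=15.0, d_ctla4=1.0, cytokines={}),
    "th1": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=5.0, cytokines={"IFNGE": 1.0}),
    "th2": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=5.0, cytokines={"IL4E": 1.0}),
    "th17": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=5.0,
                 cytokines={"TGFBE": 1.0, "IL21E": 1.0}),
    "treg": dict(a_mhc=1.0, a_cd=1.0, tau=15.0, d_ctla4=5.0,
                 cytokines={"TGFBE": 1.0, "IL10E": 1.0}),
}


def run_scenario(
    name: str,
    model: NetworkModel | None = None,
    overrides: Mapping | None = None,
    horizon: float = 60.0,
    n_points: int = 500,
    theta: float = 0.5,
    readouts: Sequence[str] = DEFAULT_READOUTS,
) -> tuple[Trajectory, RegimeLabel]:
    """Run one named scenario and classify its outcome.

    ``overrides`` may replace any preset key (``a_mhc``, ``a_cd``, ``tau``,
    ``d_ctla4``, ``cytokines``) as well as ``beta``.  Scenario metadata is
    embedded in the trajectory config.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    spec = {**SCENARIOS[name], **(overrides or {})}
    if model is None:
        model = load_tcd4(beta=spec.get("beta", None) or load_tcd4().beta)
    else:
        model = model.copy()
        if spec.get("beta"):
            model.beta = spec["beta"]
    model.set_decay("CTLA4", float(spec["d_ctla4"]))
    steps = [
        StepInput("MHC_A", avidity=spec["a_mhc"], tau=spec["tau"]),
        StepInput("CD8086", avidity=spec["a_cd"], tau=spec["tau"]),
    ]
    inputs = build_input_set(model, steps, spec.get("cytokines") or {})
    traj = simulate(model, inputs, horizon=horizon, n_points=n_points)
    traj.config["scenario"] = {"name": name, **{k: v for k, v in spec.items()}}
    label = classify_regime(traj, readouts=readouts, theta=theta)
    label.metabolic = metabolic_summary(traj)
    return traj, label


# ---------------------------------------------------------------------------
# Phase diagram
# ---------------------------------------------------------------------------


@dataclass
class PhaseDiagram:
    """Regime labels over a (tau_stim, d_CTLA4) grid, with boundary estimates.

    ``tau_boundaries`` holds the bisection-refined stimulation-time
    boundaries (no_activation -> activated, sustained -> regulated) at the
    reference decay rates used for refinement; ``threshold_curve`` maps each
    tau column to the largest scanned d_CTLA4 whose cell is regulated
    (NaN where regulation never occurs).
    """

    tau_grid: np.ndarray
    d_grid: np.ndarray
    labels: np.ndarray            # shape (len(d_grid), len(tau_grid)), dtype object
    tau_boundaries: dict[str, float] = field(default_factory=dict)
    threshold_curve: dict[float, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def category(self, tau: float, d: float) -> str:
        i = int(np.argmin(np.abs(self.d_grid - d)))
        j = int(np.argmin(np.abs(self.tau_grid - tau)))
        return self.labels[i, j]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (float(tau), float(d), self.labels[i, j])
            for i, d in enumerate(self.d_grid)
            for j, tau in enumerate(self.tau_grid)
        ]
        return pd.DataFrame(rows, columns=["tau", "d_ctla4", "category"])


def _classify_cell(model, tau, d, horizon, theta, readouts, n_points=300):
    m = model.copy()
    m.set_decay("CTLA4", d)
    steps = [StepInput("MHC_A", 1.0, tau), StepInput("CD8086", 1.0, tau)]
    inputs = build_input_set(m, steps)
    traj = simulate(m, inputs, horizon=horizon, n_points=n_points)
    return classify_regime(traj, readouts=readouts, theta=theta).category


def _bisect_tau(model, d, lo, hi, pred, horizon, theta, readouts, tol=0.1):
    """Refine the tau at which pred(category) flips from False (lo) to True (hi)."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(_classify_cell(model, mid, d, horizon, theta, readouts)):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def scan_phase_diagram(
    tau_range: tuple[float, float] = (2.0, 40.0),
    d_range: tuple[float, float] = (0.1, 5.0),
    tau_step: float = 0.5,
    n_d: int = 9,
    model: NetworkModel | None = None,
    horizon: float = 60.0,
    theta: float = 0.5,
    readouts: Sequence[str] = DEFAULT_READOUTS,
    refine: bool = True,
    d_ref_sustained: float = 5.0,
    d_ref_regulated: float = 0.5,
) -> PhaseDiagram:
    """Map activation regimes over stimulation time and CTLA-4 decay rate.

    The tau axis is linear with ``tau_step`` spacing; the d_CTLA4 axis is
    log-spaced with ``n_d`` points.  With ``refine=True`` the two tau
    boundaries are bisected to +/- 0.05 at the reference decay rates.
    """
    if tau_range[1] <= tau_range[0] or d_range[1] <= d_range[0]:
        raise ValueError("degenerate scan range")
    if tau_step <= 0 or n_d < 2:
        raise ValueError("resolution must be >= 2 per axis")
    if model is None:
        model = load_tcd4()
    tau_grid = np.arange(tau_range[0], tau_range[1] + 1e-9, tau_step)
    d_grid = np.geomspace(d_range[0], d_range[1], n_d)

    labels = np.empty((len(d_grid), len(tau_grid)), dtype=object)
    for i, d in enumerate(d_grid):
        for j, tau in enumerate(tau_grid):
            labels[i, j] = _classify_cell(model, float(tau), float(d),
                                          horizon, theta, readouts)

    diagram = PhaseDiagram(
        tau_grid=tau_grid, d_grid=d_grid, labels=labels,
        config={"horizon": horizon, "theta": theta, "readouts": tuple(readouts),
                "beta": model.beta},
    )

    # raw per-tau regulation threshold (largest scanned d that regulates)
    for j, tau in enumerate(tau_grid):
        reg = [d_grid[i] for i in range(len(d_grid)) if labels[i, j] == "regulated"]
        diagram.threshold_curve[float(tau)] = float(max(reg)) if reg else float("nan")

    if refine:
        # no-activation -> activated boundary at the sustained-reference d
        col = [_classify_cell(model, float(t), d_ref_sustained, horizon,
                              theta, readouts) for t in tau_grid]
        act = [k for k, c in enumerate(col) if c != "no_activation"]
        if act and act[0] > 0:
            k = act[0]
            diagram.tau_boundaries["activation"] = _bisect_tau(
                model, d_ref_sustained, float(tau_grid[k - 1]), float(tau_grid[k]),
                lambda c: c != "no_activation", horizon, theta, readouts)
        # sustained -> regulated boundary at the low-d reference, searched
        # from inside the sustained band (regulation re-entry comes later)
        col = [_classify_cell(model, float(t), d_ref_regulated, horizon,
                              theta, readouts) for t in tau_grid]
        sus = [k for k, c in enumerate(col) if c == "sustained"]
        reg = [k for k, c in enumerate(col)
               if c == "regulated" and sus and k > sus[0]]
        if reg and reg[0] > 0:
            k = reg[0]
            diagram.tau_boundaries["regulation"] = _bisect_tau(
                model, d_ref_regulated, float(tau_grid[k - 1]), float(tau_grid[k]),
                lambda c: c == "regulated", horizon, theta, readouts)
    return diagram
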