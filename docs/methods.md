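# Methods

## From Boolean rules to continuous dynamics

The package's core object is a rule network: one Boolean update rule per
node over `and`/`or`/`not`, with designated input nodes driven externally.
Two semantics are defined on the same rules.

**Synchronous Boolean dynamics.** All non-input nodes update
simultaneously; attractors (fixed points and cycles) are found by
exhaustive enumeration of the free-node state space when it fits under a
configurable cap (default 2²⁰ states), otherwise from seeded random
starts. Basin sizes are exact under enumeration and observed start counts
under sampling. Robustness is probed two ways: flipping bits of attractor
states and measuring the fraction of perturbed states that relax back
(plus the mean Hamming distance to the attractor along transients), and
flipping single outputs of a rule's truth table and checking whether the
attractor set is preserved.

**Continuous fuzzy dynamics.** Each rule is translated by the
product / probabilistic-sum / complement algebra (`q and p → q·p`,
`q or p → q + p − q·p`, `not p → 1 − p`), which agrees with the Boolean
rule on every {0,1} corner. The rule value drives a logistic membership
function μ[w] = 1/(1 + e^(−β(w − w_thr))), and each node k obeys
dq_k/dt = μ[w_k(q)] − d_k q_k. A node without inputs therefore decays
exponentially toward the small β-dependent floor μ(−β·w_thr)/d_k, and a
steady state satisfies q_k* = μ[w_k(q*)]/d_k. Repeated variables within
one rule are multiplied in once per occurrence — the algebraic translation
is applied literally, with no idempotence correction — and only the
product/probabilistic-sum connective pair is offered (no min/max norms).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| β | sigmoid gain (dimensionless) | 5 (library); 10 (51-node asset) | see calibration below |
| w_thr | activation threshold | 1/2 | μ(w_thr) = 1/2 exactly |
| d_k | decay rate of node k (1/time) | 1 | τ_k = 1/d_k is the characteristic expression time |
| A, D | avidity and detachment of a step input, in [0,1] | 1, D = A | full detachment after τ_stim unless overridden |
| τ_stim | stimulation time | 15 | time units of the model |
| horizon | integration length | 60 | ≈ 4 × τ_stim so post-stimulation relaxation is visible |

Levels of nodes with d_k < 1 can exceed 1 (the steady level is μ/d_k).
Before entering any rule expression the state is clamped to [0,1]:
expression beyond full saturation carries no additional regulatory weight.
This matters for CTLA-4, whose decay rate is the main scanned parameter.

## Numerical choices

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8,
atol 1e-10) with the integration split at every input discontinuity.
The step inputs are left-closed — the avidity at t = τ_stim is still A —
and each right-hand segment evaluates its inputs just inside the open
interval, so the discontinuity is handled event-exactly rather than
smoothed. Trajectories are reported on a 500-point grid by default.
Steady states are obtained by long-horizon integration followed by Newton
polishing of μ[w(q)] − d·q = 0 (residual ≤ 1e-6); an endpoint still
drifting is reported as non-convergence (oscillatory regime), distinct
from integrator failure. The adaptive integrator is cross-checked in the
test suite against an independent fixed-step RK4 (dt = 0.01) built
directly on the public fuzzy-evaluation and membership functions; the two
agree to better than 1e-4 sup-norm on the metabolism module.

## The 51-node T CD4 network: a reconstruction

The packaged metabolism module (8 rules; MTOR, MTORC1, MTORC2, LKB1,
AMPK, glycolysis, OXPHOS, AMP/ATP over the context inputs CD25, AKT,
calcium, FOXP3, exogenous IL-4) is reproduced verbatim from the published
table. The full 51-node activation network, however, is distributed by
the source study as supplementary material that could not be obtained when
this package was assembled. The file
`assets/tcd4_51_synthetic.rules` is therefore a **synthetic
reconstruction**: the node count (51), the input set (MHC–antigen,
CD80/86, and exogenous IL-4, IFN-γ, IL-10, TGF-β, IL-21), the naive-state
initial condition (OXPHOS = 0.2, AMP/ATP = 1, AMPK = 1, all signaling
nodes 0) and the qualitative dynamical repertoire follow the published
description; the individual non-metabolism rules were rebuilt from the
study's figure captions and text using canonical T-cell signaling biology.
Its load-bearing design elements:

- a TCR-proximal cascade (TCR → ZAP70 → LAT → PLCγ → Ca²⁺ → calcineurin →
  NFAT; LAT → RAS → ERK; PLCγ → PKCθ → NFκB/JNK) with coincidence
  requirements (e.g. LAT needs both ZAP70 and TCR) that filter weak,
  half-level stimulation — this is what makes A = 0.5 inputs die out
  instead of propagating at level 0.5 forever;
- an autocrine IL-2 latch (NFAT·AP-1·NFκB → IL-2 gene; NFκB/STAT5 → CD25;
  IL-2·CD25 → JAK3 → STAT5, with JAK3 feeding back into PLCγ and RAS)
  whose closure time sets the minimum stimulation time for activation;
- checkpoint wiring in which CTLA-4 expression requires late activation
  signals (NFAT·STAT5·TCR, or FOXP3 constitutively), displaces CD28 from
  CD80/86, and suppresses LAT, PI3K and JAK3 — the latch-killing route;
- an anergy arm (NDRG1 active under TCR signal with low AKT, blocking the
  IL-2 gene) and four cytokine-driven differentiation arms (T-bet, GATA3,
  RORγt, FOXP3 with their mutual inhibitions), with FOXP3 gated on NFAT
  so that Treg induction follows activation and feeds AMPK, repolarizing
  metabolism to OXPHOS.

Passing tests therefore demonstrate that *this reconstruction* reproduces
the published qualitative repertoire; they cannot certify rule-for-rule
identity with the original supplementary network.

## Calibration

The source study does not print its sigmoid gain. At the spec-level
default β = 5 the reconstruction's IL-2 latch cannot self-sustain (the
three-factor IL-2-gene product chain attenuates below threshold), so the
asset records β = 10, at which the latch has a robust high fixed point and
the phase diagram reproduces the published regime layout. The library
default for hand-built networks remains β = 5.

The activation classifier — the published figures imply but do not state a
numeric criterion — uses the pointwise **minimum** of the readout set
{NFAT, NFκB, AP1, IL2G} as the composite activation signal (the program
counts as engaged only while all of its outputs are expressed), threshold
θ = w_thr = 1/2, a tail window of the final 20% of the horizon, and a
minimum dwell of one characteristic expression time above threshold for a
trajectory to count as activated at all (threshold-grazing transients
commit nothing downstream). Categories: *no activation* (composite never
dwells above θ), *sustained* (tail mean ≥ θ), *regulated* (activated but
below θ by the tail). All four knobs are exposed as arguments.

With these settings the (τ_stim, d_CTLA4) scan over τ ∈ [2, 20]
(step 0.5, then bisection to ±0.05) and nine log-spaced d values in
[0.1, 5] yields: no activation below τ ≈ 6.6, a sustained band up to
τ ≈ 10.3 that is independent of d_CTLA4, and regulated activation beyond
it with a quasi-periodically wiggling d-threshold. Within
10 < τ ≲ 13 regulation indeed requires d_CTLA4 < 1; at τ ≈ 13–16.5 the
reconstruction also shows isolated regulated cells at d_CTLA4 ≈ 1.2–1.9
(about 4% of the scanned grid). These are stimulation-end encounters with
the first checkpoint pulse: once the latch closes, CTLA-4's drive
saturates and its plateau μ/d is near-maximal for any d ≲ 2, so in that
window pulse *timing* rather than persistence decides survival. This is a
known deviation of the reconstruction from the published claim that
regulation requires d_CTLA4 < 1 everywhere, and the corresponding
end-to-end test is expected to fail until the original rule set can be
transcribed.

## What the scenarios assume

Named scenarios drive MHC–antigen and CD80/86 with equal τ_stim = 15 and
full detachment. `optimal_sustained` uses d_CTLA4 = 5 (fast checkpoint
turnover), `checkpoint` d_CTLA4 = 0.5. The anergy scenarios halve one
avidity (A = 0.5) and keep d_CTLA4 = 1 (the study does not state a value;
checkpoint activity plays no role there). Differentiation scenarios add
the lineage cytokines (Th1: IFN-γ; Th2: IL-4; Th17: TGF-β + IL-21; Treg:
TGF-β + IL-10) on top of optimal engagement with d_CTLA4 = 5, the
"low-level CTLA-4 activity" convention. The exact exogenous-cytokine
vectors for each lineage are part of the reconstruction, chosen as the
canonical inducers among the five declared cytokine inputs.

## Problem sizes

The default test and acceptance runs use: exhaustive enumeration of the
metabolism module (2⁸ states per input context, 2⁵ contexts), 500-point
trajectories over horizon 60 for scenario runs, a 37 × 9 phase grid with
bisection refinement, and 500 sampled Boolean starts for the 51-node
attractor search. A full scenario simulation takes ~0.15 s and the phase
scan ~30 s on one core.

## Known limitations

- The 51-node asset is a reconstruction (above); quantitative boundary
  values (6.6, 10.3) should be read as approximations to the published
  7 and 10.
- Only synchronous Boolean updating is implemented; no asynchronous or
  generalized update schemes.
- No SBML-qual import/export; the plain-text rule format and the signed
  interaction-table export are the interchange surfaces.
- No stochastic dynamics, delays, or bifurcation continuation — regimes
  are mapped by direct scanning.
- Multi-valued (>2 level) logic is out of scope; fuzziness enters only
  through the continuous translation.
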