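# Methods

This note documents the models, numerical choices and study conditions
implemented in `mvsim`, and what the synthetic experiments do and do not
show about real cortical microvascular networks (MVNs).

## Blood-flow model

Flow is laminar, incompressible and quasi-steady: Poiseuille's law per
vessel and mass conservation per node. Reynolds numbers on the default
synthetic network stay below 0.05 (a diagnostic, `reynolds_numbers`, reports
them; they are never enforced). Units are µm / ms / Pa internally; mmHg is
converted at the interfaces (1 mmHg = 133.322 Pa), volumes use
1 nl = 10⁶ µm³.

Blood rheology enters through three empirical relations transcribed from
the primary in-vitro literature:

* **relative effective viscosity** `µ_rel(D, H_d)` — the 45 %-hematocrit
  curve `220 e^(−1.3D) + 3.2 − 2.44 e^(−0.06 D^0.645)` interpolated in
  hematocrit with the usual shape exponent `C(D)`; equals 1 at `H_d = 0` and
  exhibits the Fåhræus–Lindqvist minimum near 7–8 µm. Locked by regression
  tests against an independent transcription.
* **Fåhræus effect** — tube-to-discharge ratio
  `H_t/H_d = H_d + (1−H_d)(1 + 1.7 e^(−0.415D) − 0.6 e^(−0.011D))`; RBCs
  move faster than bulk blood by `H_d/H_t`. The inverse map (tube →
  discharge) is solved by fixed-point iteration.
* **phase separation** — the logit-form flux-splitting law with parameters
  `X₀ = 0.964(1−H_d)/D_f`, `B = 1 + 6.98(1−H_d)/D_f` and the
  diameter-asymmetry term `A`; applied only where the parent diameter
  exceeds 10 µm, as the law's validity requires.

Plasma viscosity defaults to 1.2·10⁻³ Pa·s (conventional for this model
family; configurable). The linear system is solved by sparse direct
factorization (conjugate gradients beyond 10⁵ nodes). Boundary conditions
are Dirichlet pressures only; every connected component must contain one,
otherwise the solver raises naming the component.

### Steady (fixed-point) mode

`fixed_point_flow_hematocrit` alternates a pressure/flow solve with a
downstream hematocrit sweep (nodes processed in order of decreasing
pressure) until the maximum flow change, relative to the local flow but
floored at 1 % of the median perfused flow, falls below `tol` (default
10⁻⁶); updates are damped by ½. Two choices deserve note:

* At divergent bifurcations with parent diameter ≤ 10 µm the discrete
  single-file routing has no deterministic flux-split analogue; the sweep
  uses a flow-proportional split, which is the long-run average of a
  routing rule that is itself flow-correlated. Above 10 µm the empirical
  law applies directly.
* Stagnant vessels (|q| ≤ 10⁻⁸ µm³/ms) keep their hematocrit — their RBCs
  are trapped. This matters for occlusion: the occluded 0.01 µm vessel
  retains blood, its relative viscosity is then O(10²), and its residual
  flow lands near 10⁻¹²–10⁻¹¹ µm³/ms, comfortably below the 10⁻¹⁰
  contract.

### Discrete-RBC mode

RBCs are point particles (volume 49 µm³, mouse; configurable, overlap
allowed) advected at `v_bulk · H_d/H_t`. At divergent bifurcations RBCs are
routed by the empirical law (as a probability) above 10 µm parent diameter
and by the largest pressure force — pressure drop × daughter cross-section,
ties to the lowest vessel id; a bare-pressure-drop alternative is
configurable — below it. Vessel hematocrits are recomputed from counts each
step and fed back into the viscosities (`feedback=False` freezes the
hematocrit at the inflow value, making the time average equal the steady
solve to machine precision — a test anchor). The time step is
0.8 × min(L/v_RBC) capped at 1 ms, so no RBC can skip a vessel. RBCs are
injected at inflow boundaries to match the inflow discharge hematocrit via
per-boundary accumulators, and a strict count ledger (injected − removed −
present = 0) is asserted in tests. One turnover time is the first time 85 %
of vessels have cumulatively passed their own lumen volume; averages run
over `n_turnovers` turnovers after a burn-in of one turnover (the
simulation is already past its initial transient by then; the turnover
criterion itself requires near-global perfusion).

A fidelity note: RBCs influence resistance only through the per-vessel
hematocrit-mean viscosity, not as discrete resistive elements; this is the
main knob separating this implementation from finer-grained RBC models. In
small motif fixtures the deterministic single-file rule can drive all cells
into one branch (a stable plug); this is a real behaviour of the rule
family, and the motif tests account for it.

## Microstroke protocol

Occlusion sets the MSC diameter to 0.01 µm (reversible; originals kept).
Baseline and stroke use identical boundary pressures and, in RBC mode, the
same seed. The thresholded relative change uses absolute flows with a hard
zero below `th_abs` = 0.1 µm³/ms (0.2 RBC/s for flux); direction changes are
tracked separately; a zero baseline makes the relative change undefined
(NaN, excluded from aggregates). MSC candidates pass six conjunctive
criteria (cylinder radius 444 µm around the x-y centroid of the node cloud;
mean flow > 0.16 µm³/ms; mean hematocrit > 0.02; direction-change
frequencies ≤ 5/10/30 % at the MSC / generation ±1 / generations ±2–3;
≥ 3 segments from both penetrating main branches, where "k segments apart"
is the vessel-adjacency BFS distance with 0 on the main branch itself; and
a vessel bounding box ≤ 0.2 nl); the count surviving each criterion is
reported in order. Case filters (e.g. a baseline-flow window) are optional
config fields.

The sequential multi-occlusion experiment uses the 0.3 nl box around the
MSC (> 12 capillaries required), occluding after each stage the two
non-occluded box capillaries with the lowest current |q| until nine are
blocked.

## Local topology

Generations follow baseline flow directions breadth-first from the MSC
endpoints, first assignment wins, upstream preferred on equal depth.
Analysis boxes grow from the MSC's axis-aligned bounding box by the same
distance on all sides (monotone cubic root, Brent, 10⁻⁶ relative). Box
inflow counts every outside→inside crossing of a centerline walked along
the flow (multi-crossing vessels contribute per crossing); total box flow is
Σ |q| × clipped centerline length, with the polyline rescaled so its arc
length matches the nominal (tortuosity-consistent) vessel length. The
vessel categories partition the box: the MSC with its generations ±1…±5
("updown"), vessels branching off/into generation-1/2 vessels followed three
segments along the flow ("parallel"), and the rest ("distant"). The tissue
grid assigns every 4 µm cell center to the nearest centerline point (1.3 µm
sampling; exact ties resolve to the lowest vessel id via point ordering);
supplied volumes therefore partition the grid exactly.

## AV-factor and flow paths

The flow-direction DAG keeps vessels with |q| above 10⁻⁸ µm³/ms (below
that, direction is numerical noise), asserts acyclicity, and defines DA/AV
endpoints as the first node of degree ≥ 3 reached walking off the main
branch. Path counts use the standard topological-order DP with Python
integers (exact at any magnitude); per-edge counts are `U(tail)·W(head)`;
explicit enumeration exists only as a test oracle. Endpoint pairs connected
during stroke solely through the (stagnant) MSC are excluded from the
category analysis; "unique paths" counts paths differing in any vessel as
distinct.

The AV-factor of a capillary is `medDA/(medDA + medAV)` where the medians
run over the multiset of *path lengths* from the capillary to all reachable
DA (upstream) and AV (downstream) endpoints, each plus half the capillary's
own length (making the factor strictly monotone along an unbranched chain);
a per-endpoint-shortest variant was considered and rejected as less
informative about the path ensemble. Three computation modes: exhaustive
enumeration (capped; fixtures), DP path sampling weighted by path counts
(unbiased), and the default *histogram DP* — exact weighted path-length
distributions propagated through the DAG in fixed bins (0.5–2 µm), which is
both faster and tighter than sampling at network scale; the three agree on
fixtures within the bin width. Proximity analyses (nearest-vessel and
nearest-arteriole-sided distances, 50 µm sphere scans, 30–120 µm cube scans
with half-side overlap and the ≥ 4-capillaries / ≥ 50 %-coverage
eligibility rules) operate on the 1.3 µm point sampling, not exact segment
distances.

## Synthetic study conditions

The generator emulates the statistical structure the analyses assume, not
any particular reconstruction:

* jittered cubic lattice (default 10×10×10, spacing 34 µm, jitter 6 %)
  diluted from a random spanning tree toward degree-3 bifurcations —
  guaranteed connected, predominantly 3-connected interior;
* capillary diameters lognormal (mean 5 µm, cv 0.2 → ~4–7 µm) and lengths
  lognormal (mean 62 µm, cv 0.2 → ~40–90 µm), realized by sine-bump
  tortuous centerlines whose arc length matches the drawn length (chord
  floor on the ~1 % of draws shorter than the jittered chord);
* two DA and two AV penetrating trees: tapering main-branch trunks
  (12→7 µm and 16→9 µm), ~7–8.5 µm offshoots to nearby lattice nodes, and
  a pial feeding segment (6 µm × 300 µm) acting as the lumped resistance of
  the unresolved upstream vasculature;
* Dirichlet pressures: 60 mmHg at DA roots, 15 mmHg at AV roots, and cut
  capillary stubs on the faces interpolated in the capillary range
  (36→32 mmHg by topological distance between the trees, ±0.5 mmHg noise);
  inflow discharge hematocrit 0.3.

Under these defaults the capillary flow distribution is heterogeneous with
a median near 2 µm³/ms (5th–95th percentile roughly 0.1–14), all four MSC
types occur with ≥ 20 eligible candidates each, and the rarest type
(2-in-2-out) sits near 10 % of eligible capillaries. These conditions were
fixed once, before the downstream experiments were evaluated.

What passing tests do *not* show: the lattice has neither the layered
density gradients, the long-range correlations, nor the reconstruction
artifacts of imaged MVNs; absolute magnitudes (path counts, supplied
volumes, deficit percentages) are specific to these synthetic conditions
and should be read as qualitative signatures (orderings, signs, monotone
trends), not as predictions for real tissue.

## Problem sizes

The test suite and the acceptance script run the stroke campaigns in steady
mode on the 10×10×10 lattice (≈ 1 900 vessels) with 20 occlusions per MSC
type, and the discrete-RBC protocol on ≤ 12-vessel motifs over 2–3
turnovers; these sizes give stable medians for the qualitative contracts
while keeping a full run in the tens of seconds. Bootstrap confidence
intervals use 10⁴ seeded resamples by default.

## Known limitations

No vessel compliance, pulsatility, active diameter regulation or
biological occlusion mechanism (occlusion is instantaneous and permanent);
no oxygen transport — conclusions concern perfusion only; the topological
supplied tissue volume ignores oxygen-weighted effectiveness; RBC mechanics
are point-particle; the hierarchical boundary-condition embedding of real
reconstructions is replaced by prescribed pressures, so loaders of real
networks must supply their own boundary values.
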