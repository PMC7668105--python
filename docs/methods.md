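# Methods

This note documents the models implemented in `hemonet`, their assumptions,
the parameters that matter, and the choices made where the design was
genuinely open.

## Network model

A vascular network is a directed multigraph of nodes (optional 2D positions,
micrometres) and straight vessel segments with length `L` and diameter `d`.
Segment orientation is the nominal flow direction; solvers may return
negative flows and never rewrite topology.  Coordinates are required only by
the oxygen module.  Only diverging (1→2) and converging (2→1) junctions are
modelled; trifurcations, three-to-two mergers and flow-directed cycles are
detected and rejected rather than approximated.

## Blood rheology and network flow

Flow is laminar Poiseuille flow by analogy with Ohm's law: conductance
`g = pi d^4 / (128 mu L)`, Kirchhoff balance at interior nodes, Dirichlet
pressures and/or Neumann flows at boundary nodes (at least one pressure
fixes the gauge; all-flow boundary sets must balance exactly and are
otherwise rejected).  The apparent viscosity is
`mu = mu_plasma * mu_rel(d, H)` with the standard empirical in-vivo
relative-viscosity law (reference apparent viscosity at 45% discharge
hematocrit, a diameter-dependent shape exponent for the hematocrit
dependence, and a squared `d/(d − 1.1 um)` factor for the endothelial
surface layer).  `mu_plasma` defaults to 1.2 mPa·s.  Only discharge
hematocrit is represented; the tube/discharge distinction is out of scope.

### Coupled iteration

Flow and hematocrit are coupled through the viscosity.  `coupled_solve`
iterates: linear flow solve → topological hematocrit propagation →
under-relaxed update (factor 0.5, tolerance 1e-8, at most 500 iterations).
The first pass and any pass in which the flow field is already stationary
take a full (unrelaxed) hematocrit step, so the decoupled
(hematocrit-independent viscosity) limit converges in at most two outer
iterations — one of which is pure verification — and a symmetric network
converges in one.  The returned hematocrit field is the freshly propagated
one, so red-cell flux balance holds to machine precision for the returned
flows.  Hematocrit is capped at 0.95 with a logged warning (never triggered
in the default experiments); segments carrying less than 1e-14 of the peak
flow are treated as unperfused (`H = 0`) and excluded from split
bookkeeping.  An exact recurrence of an earlier hematocrit iterate aborts
with an oscillation diagnosis instead of averaging silently.

## Hematocrit splitting

At a diverging bifurcation the red-cell flux fraction `FQE` entering a
branch follows the classical empirical logit law in the blood-flow fraction
`FQB` (see README for the formulas).  The in-vivo base parameters are

    A  = −13.29 [(d_f/d_u)^2 − 1]/[(d_f/d_u)^2 + 1] (1 − H_P)/d_P
    B  = 1 + 6.98 (1 − H_P)/d_P
    X0 = 0.964 (1 − H_P)/d_P

with diameters in micrometres.  `A` vanishes for equal child diameters, so
in the symmetric synthetic trees all no-memory asymmetry is zero by
construction.  Parent diameters small enough to push `X0` to 0.5 are outside
the parametrization's validity and raise.

### Memory effects

Each segment carries a cell-free-layer state: the side of its cross-section
with the thinner (disrupted) CFL, the distance travelled since the upstream
diverging bifurcation in vessel diameters, and the relation of its
downstream bifurcation plane to the upstream one.  The disrupted side at
birth is the side facing the sibling offtake — the sibling skims the
near-wall plasma there, leaving red-cell-rich core fluid near that wall.
For a perpendicular offtake the same rule places the disruption on the
outer wall of the turn.  At the next bifurcation the child that samples the
parent's disrupted side is *favorable*; converging junctions reset the state
to symmetric, and pass-through nodes accumulate distance `L/d`.

The favorable/unfavorable parameter modulation decays exponentially with a
single recovery length `s_hat` (see README).  The exponential ansatz is the
minimal monotone recovery model consistent with the reported CFL dynamics;
the true functional form is not published.  The amplitudes are fitted by
unweighted least squares to the second-bifurcation discharge hematocrits of
the three benchmark geometries (double-t and cross at 4 diameters, extended
double-t at 25 diameters, measured parent hematocrit ≈ 20%, equal flow
split, channel diameter 20 um).  The fit gives `dA = 0.483`,
`s_hat = 7.63` diameters, `beta ≈ 0`: at an equal flow split the `X0`
modulation is nearly collinear with the `A` modulation, so the data cannot
identify `beta` separately and the fit assigns the whole effect to the `A`
channel.  The frozen defaults reproduce the benchmark favorable/unfavorable
pairs within two standard errors and leave the extended double-t split
within 0.35 hematocrit points of even.  A secondary streamline-split
asymmetry observed at fully recovered bifurcations (~19.2% vs 20.8%) is
deliberately not modelled; `A` retains only its diameter-asymmetry term.

Ties (equal flows, symmetric parameters) are labelled
favorable/unfavorable deterministically by segment id; the labels are inert
because the split is even.

## Synthetic vasculature

`build_symmetric_tree` constructs a Murray's-law double tree: one inlet
vessel (generation 0), `G` diverging generations with equal child diameters
`d_c = d_p·2^(−1/3)`, every vessel at `L = lambda·d`, then a converging half
that mirrors the diverging half into a single outlet.  The converging half
is a translated reversed copy of the diverging half (countercurrent partner
vessels offset by a quarter inlet diameter) whose deepest segments start at
the shared leaf nodes; the total segment count is `2^(G+2) − 2`.  Every
bifurcation uses the benchmark motif — a straight continuation plus a
perpendicular offtake — and the per-generation pattern fixes the offtake
side relative to the parent's disrupted-CFL side: `double-t` = same side
(side branch favorable), `cross` = opposite side (straight branch
favorable), `perpendicular` = out-of-plane (no inherited asymmetry).  The
default is double-t everywhere, the canonical configuration of the
benchmark experiments; branches of distinct subtrees may cross in the
plane, which carries no topological meaning.  Defaults: 6 diverging
generations, 50 um inlet diameter, 1 um diameter floor.

The benchmark geometries themselves (`build_benchmark_geometry`) are
channels 0–4 with lengths `(25d, delta, 25d, 25d, 25d)`,
`delta = 4d` (double-t, cross) or `25d` (extended double-t), side-branch
angles `pi/2` or `3pi/2`, and annotated outlet flow fractions
`Q2 = Q0/2`, `Q3 = Q4 = Q0/4` for an equal split at both bifurcations.  The
channel diameter is a free parameter (default 20 um).

`generate_morphology_table` draws per-vessel lengths and diameters from
independent log-normals.  Defaults target the measured MC38 allograft group
means (128.6 um, 33.0 um) with log-scale standard deviations 0.60 and 0.45
— right-skewed marginals of realistic spread.  What the generator does
*not* emulate: spatial correlation along branches, diameter–generation
trends, perfusion heterogeneity.  A green statistical test on these tables
establishes the estimator's behaviour, not biological truth.

## Tissue oxygen

Steady state `0 = D lap(c) + S − k c` on a cell-centered grid with no-flux
boundaries (5-point stencil, sparse direct solve).  `S` adds
`q·H·(intersected length)/(cell area)` for every vessel crossing a cell, a
conservative rasterization: the total source equals `q·sum(H L)` exactly.
Consumption is first order in `c` (the linear-sink description is taken as
authoritative over a constant-rate paraphrase elsewhere; with constant-rate
sinks and no-flux walls a steady state would not generally exist).
Defaults: `D = 2000 um^2/s`, `k = 0.8 /s` — diffusion length
`sqrt(D/k) = 50 um`, matching the ~100 um viable tumour-cord thickness —
and `q = 1` in arbitrary concentration units.  Grid spacing must not exceed
half the minimum vessel diameter; the default domain adds one diffusion
length of margin around the network bounding box, and odd grid dimensions
center the grid so mirror-symmetric networks yield mirror-symmetric fields.

The analysis region is the centered rectangle holding 25% of the domain
area.  `compare_distributions` reports dispersion summaries (SD, IQR,
quartiles) and a two-sided two-sample test (Mann–Whitney by default; Welch
and Kolmogorov–Smirnov selectable).  By default every ROI grid value enters
the test; because neighbouring cells are spatially correlated, these
p-values measure how distinguishable the two fields are, not
independent-sample evidence.  Seeded subsampling (`max_samples`) is
available for a conservative reading.

## Lambda sweep

For each `lambda` in {4, 5.5, 7, 8.5, 10} and each splitting rule, the
pipeline builds the tree, solves the coupled problem, solves oxygen on the
network-fitted domain and summarizes the ROI.  With memory effects the ROI
IQR decreases monotonically from `lambda = 4` to 10 and exceeds the
no-memory IQR at every `lambda`; the cross-rule difference is significant at
`lambda = 4` (p ≈ 4e-4) and not at `lambda = 10` (p ≈ 0.051).  A known
limitation: because line-source strength is fixed per unit vessel length
while the tissue domain area grows as `lambda^2`, the overall concentration
scale falls roughly as `1/lambda`; in absolute units the no-memory IQR
therefore also decreases with `lambda`, and the expected opposite
(increasing) geometric trend appears only in mean-relative dispersion.
Pinning perivascular oxygen (exchange-type vessel coupling) would decouple
the scale from `lambda`, but lies outside the source model implemented
here.

Results CSVs embed a hash of the configuration and the package version;
re-running a configuration reproduces them byte-identically.

## Known limitations

- 2D tissue and planar embeddings; the bifurcation-plane angle enters only
  through the discrete coplanar/perpendicular metadata.
- The memory calibration rests on one operating point (inlet hematocrit
  ≈ 20%, equal flow splits, one capillary number); extrapolation to other
  regimes is untested.
- Oxygen is in arbitrary units (no hemoglobin saturation kinetics, no
  intravascular resistance, no mmHg calibration).
- Complex junctions beyond 1→2 / 2→1 are rejected, not modelled.
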