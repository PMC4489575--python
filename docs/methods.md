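# Methods

## Model and assumptions

Tumor particles shed into the portal venous system are modelled as
independent random walkers. The portal tree is a rooted set of straight
cylinders; each cylinder is sliced into circular cross-sections whose
axial extent tends to zero, so motion decomposes into an in-plane walk and
a longitudinal drift constrained perpendicular to the slice (the
least-action condition: the work `dw = F·ds` with `ds = dD·sinθ` is
minimised when the displacement is normal to every in-plane curve, i.e. at
θ = π, where the literal product form gives ds = 0 — a geometric oddity of
the stated relation that we implement as printed and note here).

The in-plane walk takes unit steps in one of `N = 360k` equally spaced
directions, drawn i.i.d. uniformly per time interval. `k` is reciprocal to
the arc (degrees) spanned by one direction, so the direction set is only
defined when `360k` is an integer ≥ 2; non-conforming `k` is rejected, not
rounded. The fixed-path probability is `(1/(360k))^n`. Two further effects
modulate the event:

- **Reynolds acceleration.** `Re = ρvD/μ` per segment (diameters in mm in
  configs, converted to SI). Regimes: `[0,40)` laminar without vortices,
  `[40,2300]` laminar with vortices, `(2300,4000)` transition, `[4000,∞)`
  turbulent — the boundary placement follows the printed inequalities
  (2300 laminar, 4000 turbulent), and the vortex onset "approximately 40"
  is a hard, configurable default. Eddies shorten the walk by `m` steps;
  since the per-step probability is below 1, the `(n−m)`-step path is
  strictly more probable (the mathematically forced direction of the
  comparison, which the surrounding argument also requires). The Re→m map
  is the model's only invented functional form: a clamped-linear ramp
  `m = ⌊m_max·clamp((Re−40)/(4000−40),0,1)⌋`, fully parameterised so any
  monotone non-decreasing map can be substituted.
- **Density gate and distance.** `ρ_m` is the minimum uniform density for
  thrombus formation; `ρ_i < ρ_m` excludes a cross-section regardless of
  Re. The model constrains the origin-to-collision distance only by
  "denser ⇒ closer"; we fix the weakest defensible closed form, the 2-D
  uniform nearest-neighbour scaling `p = p₀√(ρ_m/ρ_i)` (verified in the
  tests against simulated uniform point sets), with a pluggable
  monotone-decreasing replacement hook.

Required steps per state: `i = max(1, ⌈p/step⌉ − m)`, floored at one step
because a collision event requires at least one step. Aggregating states
over time (the fourth dimension) gives

    log p(R⁴) = Σ_m i(m)·log(1/(360k)) + L·log(1/2),

with `L` the number of collision points along the particle's path whose
longitudinal approach is unidirectional (each contributes ½; `L` is
derived by summing the `longitudinal_unidirectional` segment flags along
the root-to-segment chain). All probabilities live in log space:
`(1/360)^n` underflows doubles near n ≈ 120, far below relevant step
counts; the acceptance tests demonstrate both the ≤1e−12 agreement with
exact rational products at small n and the underflow of the direct product
at Σi = 10⁴.

**Ranking convention.** The likeliest collision site is the segment with
the *maximal* `log p(R⁴)` — the same direction as the step-count argument
(fewest steps ⇒ likeliest collision; `s < i` favours the main portal
vein). A minimal-probability ordering is also exportable
(`rank_sites(..., ascending=True)`) for users who want the opposite
reading. Ties: equal scores break lexicographically by segment id; the
`s = i` comparison is declared indeterminate rather than forced.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| ρ (blood) | mass density | 1050 kg/m³ | standard whole-blood value |
| μ | dynamic viscosity | 3.5 mPa·s | standard whole-blood value |
| trunk D, v | main portal vein | 13 mm, 0.26 m/s | clinical calibre/velocity; gives Re = 1014, at the low end of the reported main-portal range (≈1020–2600) |
| k | direction resolution | 1 (360 directions) | 1° arcs; `k = 1/90` (4 directions) is the enumerable reference |
| step_length | walk unit | 1 | the walk's own distance unit |
| m_max, onset, saturation | Re→m ramp | 5, 40, 4000 | spans vortex onset to persistent turbulence |
| ρ_m, p₀ | gate, reference distance | config-required (fixture: 1, 6) | p₀ = 6 unit steps keeps fixture step counts small and distinct |
| ω | pulsation | 7.54 rad/s | 72 bpm; trunk α ≈ 9.8 < 10, quasi-steady |
| n_states_per_segment | slices contributing to p(R⁴) | 1 | the zero-length limit is not computable literally; one representative slice per segment, config-controlled |
| MC z | comparison bound | 3σ | standard Monte-Carlo tolerance |
| recover_k α | uniformity significance | 0.01 | conventional; yields ≥95% replicate coverage by binomial coverage |

## Synthetic fixture

`generate_fixture_tree` emulates a 2–3-level portal tree: binary
branching, child diameters a seeded 0.6–0.8 fraction of the parent's (the
trunk diameter is strictly maximal by construction), child velocity scaled
with diameter so Re decreases with depth. It does **not** emulate curved
centerlines, tapering within a segment, pulsatile waveforms, non-Newtonian
rheology, or patient-derived anatomy; passing tests therefore show the
pipeline's internal consistency and its qualitative headline (trunk
predicted under uniform density; prediction moves distally when density
does), not quantitative agreement with any patient geometry.

## Numerical choices

- Log-space throughout; user-facing tables report log10.
- Seeds: a single global seed fans out via `SeedSequence([seed, counter])`
  reduced to 31 bits (`config.subseed`), so each sub-computation is
  independently reproducible.
- Direction indices map to angles `2πj/N`; the MC oracle validates the
  fixed-path reading of the closed form (the only reading the formula
  supports); first-passage collision rates are simulation-only quantities
  with no analytic counterpart claimed.
- Wall collisions are collision events but tallied separately from
  particle collisions.
- Degenerate inputs: `max_steps = 0` yields a no-collision walk of just
  the origin; an all-gated tree yields an explicit `no_thrombus` status
  with a header-only ranking; a zero energy-contour sum is parallel to
  nothing.
- Hepatofugal orientation flips the longitudinal drift sign only; the
  in-plane walk is isotropic either way, so rankings are
  orientation-invariant by construction.

## Problem sizes

The test suite uses the 4-direction walk (n ≤ 3, exhaustively enumerable;
10⁵ walkers for MC checks), 10⁵-step direction histograms with 100
replicates for parameter recovery, and 3-level (7-segment) fixture trees —
sizes chosen so every check is exact or tightly powered at desk scale.

## Known limitations

- The Re→m ramp and the ρ→distance map are modelling choices constrained
  only by monotonicity; conclusions should be read as orderings, not
  magnitudes.
- One representative cross-section per segment by default; the model's
  "every instantaneous state" limit is not literally computable.
- No CFD: velocities are user inputs per segment, not solved; no
  wall-shear stress, no vessel-wall compliance (justified by α < 10).
- ρ_m is a free parameter; the package makes no attempt to estimate it
  from clinical data.
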