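# Methods

## Data model and conventions

A flow study consists of a 4D velocity field (per-voxel 3-vectors, mm/s) on
a regular Cartesian grid, binary LV masks at ED and ES on the same grid, a
basal-plane definition with inlet/outlet regions, and timing (RR interval,
ED/ES frame indices). World coordinates are in mm with the centre of voxel
(0,0,0) at the stored origin; masks are voxel-centre sets and point-in-mask
means nearest-voxel membership. Time is cyclic on [0, RR): retrospectively
gated data wrap, so the last frame interpolates linearly to the first and
every temporal query is reduced modulo RR. Volumes are exchanged as NIfTI
with an mm affine plus a versioned JSON sidecar (`ventriflow-study/1`).

Velocity sampling is trilinear in space and linear in time. It reproduces
stored frame values exactly at voxel centres and frame times, and any field
affine in (x, y, z, t) exactly at interior points. Positions outside the
voxel-centre hull return a zero vector with an out-of-domain flag instead of
extrapolating: extrapolation can produce unbounded trajectories, whereas a
flagged, frozen pathline is handled explicitly by the aberrant rule below.
Inputs are assumed free of phase-offset and concomitant-gradient errors
(such corrections belong to scanner-side preprocessing).

The basal geometry is one oriented plane (normal pointing away from the LV)
carrying two disjoint discs for the mitral and aortic orifices. Discs may
optionally carry their own normal, in which case each defines its own
crossing plane; this generalisation exists so the straight-channel phantom
can expose its entry and exit faces as two parallel port planes while the
anatomical case keeps a single basal plane.

## Pathline tracing

One pathline is seeded at every ED-mask voxel centre and carries exactly one
voxel volume, so the traced set partitions the LVEDV by construction.
Integration is classical fixed-step RK4 on dx/dt = v(x, t); backward legs
use a negative step, which is exactly time-symmetric. The step is one
frame interval divided by `substeps` (default 10 — about 5 ms at a typical
52–53 ms temporal resolution). A fixed step keeps results deterministic and
lets convergence be measured directly: on a solid-body rotation field the
observed order is ≈ 4.0, and forward-then-backward integration returns to
the seed within 10⁻⁹ mm. Each seed is traced backward from ED to the
previous ES (diastole) and forward from ED to the next ES (systole), with
samples recorded at frame times and crossing checks at every substep.

Crossings are detected from sign changes of the plane's signed distance
between consecutive substep states; the crossing point and time come from
linear interpolation along the step and are labelled inlet/outlet/wall from
the in-plane position. A point exactly on the plane counts as LV-interior — a
deterministic, measure-zero tie rule. A pathline that leaves the grid hull is
frozen at its exit point, flagged, and later labelled aberrant; this replaces
interactive visual screening of traces with an automatable rule. The ES mask
is not consulted during integration: the basal plane is the single
authoritative exit surface.

## Classification and aggregation

"Entered" means the backward trajectory crosses the basal surface through
the inlet region; "ejected" means the forward trajectory crosses through the
outlet region. Labels follow the four-way transit definition (DF, RI, DEF,
RV); pathlines that left the grid or crossed the basal surface outside both
regions (wall crossings) are labelled aberrant. When a trajectory crosses
several times — flow dipping into the atrium and returning — the default
`net` rule lets the last crossing before the horizon decide the state there,
reading transit as a net statement over the cycle; a `first`-crossing rule is
available in configuration, and the two agree whenever no re-entry occurs.

Volumes are summed per label; ratios are always reported against the full
LVEDV. If aberrant pathlines exceed 1 % of the volume a warning is logged,
since the remaining ratios then understate their components. The
conservation QC uses the symmetric relative difference
|inflow − outflow| / mean(inflow, outflow) — the screening rule that
motivates it states only a percentage difference, so the symmetric
denominator is a documented choice — with failure above 0.10; zero flow in
both directions is reported as an undefined-QC failure rather than a pass.

## Kinetic energy

KE per pathline is ½·ρ·V·|v|² with ρ_blood = 1060 kg/m³, reported in mJ
(1 m³ at 1 m/s gives exactly 530 J, which the unit audit asserts). Component
curves sum pathline energies per label on the common frame-time grid; the
total sums all non-aberrant pathlines, so component curves add to the total
identically. Pathlines frozen outside the grid contribute zero after their
exit. ED KE ratios divide component KE at the ED sample — the seed sample,
so speeds are stored frame values at voxel centres, with no interpolation
asymmetry — by total KE at ED; a zero total is reported as missing with a
reason. KE is not integrated over time: the analysis uses the curves plus
the ED snapshot only. When all pathlines share one speed the KE ratios
reduce exactly to the volume ratios.

## Phantoms

**Plug flow.** A straight channel of length L with uniform axial speed v,
zero velocity outside, quiescent margin voxels beyond each face, and ED set
mid-cycle so both tracing directions are exercised. With inflow reach
d_in = v·T_d and ejection reach d_out = v·T_s, a parcel at distance x from
the entry face entered iff x < d_in and is ejected iff x > L − d_out, giving
closed-form fractions by interval arithmetic (flush regime when both
reaches exceed L). Trajectories are trivial, so this isolates classification:
across a 21-point grid spanning stagnant, disjoint, overlapping and flush
regimes the pipeline matches the closed form within half a voxel layer per
interface (observed ≤ 0.005; the design bound is one voxel layer,
spacing/L, per interface). The default 20 frames per cycle put the default
substep near the step-to-voxel ratio of clinical configurations; with very
few frames the frame-interval-based step rule would make steps of several
voxels and thicken the boundary layer at the faces.

**Chamber.** An ellipsoidal chamber (≈142 ml below the basal plane, matching
typical LVEDV) under a plane carrying a diastolic inflow jet and a systolic
outflow jet on disjoint discs, plus a persistent horizontal swirl so the ED
velocity snapshot is non-zero. Each jet derives from a Stokes streamfunction
Ψ = ±(q/2π)·S(r)·g(z): S gives a parabolic core profile that is identically
zero beyond the core radius (so plane crossings stay inside the port
regions), and g(z) rises from 0 at depth to 1 well below the plane, so the
jet is purely axial where it crosses and turns radial (divergence-free) over
a deep band inside the chamber. The half-sine flux envelopes integrate
exactly to the prescribed inflow (60 ml) and outflow (59 ml) volumes —
stroke-volume-scale filling with a small built-in conservation discrepancy
(QC ≈ 0.04, well inside the 0.10 gate). Above the plane a smooth envelope
damps the jets so crossed parcels park inside the grid instead of streaming
out of it. Peak jet speeds stay near 1 m/s, inside a 120 cm/s encoding
range. The geometry (port offsets ±10 mm, core radius 8 mm, depth band −8 to
−48 mm) was chosen so the volume delivered through the plane is deposited
inside the chamber mask: the pathline-measured inflow (DF + RI) then agrees
with the time-integrated basal-plane flux within ≈ 4 %. There is no closed
form; ground truth is a re-trace of the same gridded field at a 10× finer
step, with which the default step agrees to ≈ 2·10⁻⁴ of LVEDV per component.

What the phantoms do **not** emulate: wall motion (masks are static, so
global incompressibility with net inflow is impossible — the jets are
locally divergence-free near the plane and deposit/draw volume in a deep
band), velocity noise and aliasing of the encoding (optional additive
Gaussian noise exists but is not validated against scanner data),
trabeculation, valve geometry, or realistic vortex dynamics. Passing tests
therefore demonstrate correctness of interpolation, integration,
classification, aggregation and energetics on smooth fields — not robustness
to acquisition artefacts.

**Synthetic cohort.** Per-subject tables drawn at published-cohort scale:
26 patients / 10 controls by default, controls with LVEDVI 74 ± 9 ml/m² and
DF volume ratio 0.42 ± 0.08, patients 66 ± 13 and 0.40 ± 0.07, LVEF 64 ± 6 /
61 ± 7 %, heights and weights at cohort means. Within each group (LVEDVI,
DF ratio) are bivariate normal at a target correlation (default −0.64); the
DEF ratio is drawn independently and NE = 1 − DF − DEF, clipped to [0, 1]
with the clipping rate recorded in the table provenance. KE ratios are
linear functions of the volume ratios plus noise, calibrated to the
published subgroup means. Inflow is 67 ± 12 ml with outflow 1 ml lower plus
noise, so the paired test sees a small true difference. All randomness sits
behind one integer seed; generators are pure functions of (params, seed).

## Statistics stage

Pearson correlations use pairwise-complete observations and a t-distributed
two-sided p with n − 2 degrees of freedom; zero-variance variables are
reported as missing rather than erroring. The two-group comparison applies a
Shapiro–Wilk gate at α = 0.05 per group (the source rule names only
"non-Gaussian distribution", so the gate is a documented choice) to choose
between a Welch t-test (pooled-variance optional) and a Mann–Whitney U test
with normal approximation and tie correction. Subgroup analysis partitions
patients at the LVEDVI cutoff (74 ml/m², boundary assigned to the lower
group; the higher group is strictly > 74) or by LGE status, requires all
three strata (controls plus two patient groups) to be present with ≥ 2
members, and runs one-way ANOVA with Tukey HSD adjusted pairwise p-values.
Which population the published correlation table pools is ambiguous, so the
report emits both all-subjects and patients-only correlations, flagged by a
`population` column. No multiple-testing correction is applied across the
correlation table by default; a Holm adjustment is available. Missing data:
pairwise deletion for correlations, listwise within group tests, with the
record counts used always reported.

## Problem sizes and runtime

Default analyses trace ~6,500 pathlines (2.8 mm voxels) over 19 frames with
10 substeps in a few seconds; the 10× oracle re-trace takes ~30 s. The
statistics recovery uses a 10,000-patient synthetic cohort and 200 Tukey
replicates of 3 × 50 observations. The full test suite runs in ~1.5 min and
the acceptance script in ~1.5 min on one CPU.

## Known limitations

* Single-cycle transit only: no multi-cycle residence times or atrial/right
  ventricular analysis.
* Entered/ejected are decided solely by basal-plane crossings; pathological
  flow through the wall of a poor segmentation shows up only as aberrant
  volume.
* The chamber phantom's compressible deposition band means its component
  fractions are phantom properties, not physiological predictions.
* KE ratios at ED depend on the stored frame velocity at seed voxels;
  partial-volume effects at the endocardial border are not modelled.
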