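# Methods

## Input model and coordinates

The analysis consumes manually traced kymograph tracks: ordered
(time, position) polylines, one per motor complex, with time in seconds
from movie start and position in nanometers along the microtubule axis.
After orientation (using the polarity recorded per kymograph, as
established experimentally with a plus-end-directed motor), positive *x*
points to the microtubule plus end. Pixel/frame → nm/s conversion happens
at read time using the context's `pixel_size_nm` and `frame_interval_s`;
all downstream thresholds are stated in nm and s, so no default pixel size
is assumed — the context must supply it.

Speeds are evaluated on the traced segments as drawn (vertex to vertex),
which matches multisegment manual tracing. The traced line, not the
per-frame localization series, is the unit of analysis; the simulator's
`trace_tracks` reproduces exactly this reduction (below).

## Segmentation and classification rules

A segment is static iff |Δx/Δt| < `static_speed_nm_s` (default 25 nm s⁻¹,
strict); consecutive moving segments of equal sign merge into runs; every
segment belongs to exactly one run or pause, so durations partition the
track's dwell time exactly. Classification applies, in order:

1. total run length < `static_total_nm` (1,000 nm, strict) → static;
2. runs in one direction only → that direction;
3. > `bidirectional_nm` (1,500 nm, strict) in **both** directions →
   bidirectional;
4. otherwise the majority direction.

Boundary semantics: a value exactly at a threshold is *not* below it —
|speed| = 25 nm s⁻¹ counts as moving, a 1,000 nm track is not static, and
1,500 nm each way is not bidirectional. An exact plus/minus run-length tie
in rule 4 (possible only for contrived inputs) is reported as bidirectional
with a warning, since any directional choice would be arbitrary.

Note on threshold monotonicity: raising the static speed threshold can only
shrink the total run length and moving time, but it can *increase* the
number of runs — a slow segment inside a run that goes static splits the
run in two. The property tests assert the monotone quantities.

## Metrics and unit conventions

Dwell time = total time on the microtubule (pauses included). Total run
length = Σ|run length|. Average speed = total run length / dwell time
(zero for a pure pause). Two rate conventions coexist deliberately:

* landing rate = *n*<sub>tracks</sub> / (width<sub>nm</sub> ×
  duration<sub>s</sub>) × 60,000, in events µm⁻¹ min⁻¹;
* processive-event frequency = *n*<sub>events</sub> /
  (length<sub>µm</sub> × duration<sub>s</sub>), in events µm⁻¹ s⁻¹.

They differ exactly by the factor 60 and every results column carries its
units in its name. A processive event is an association lasting ≥ 1.2 s
with displacement ≥ 525 nm (both inclusive). 525 nm is five 105 nm pixels;
the 1.2 s temporal cut-off is taken at face value even though five 0.136 s
frames would be only 0.68 s — the stricter stated value is the default and
both thresholds are parameters. Displacement means total run length by
default (consistent with the five-pixels-of-trace rationale); a
net-displacement mode exists behind a flag and is stricter for
direction-switching complexes.

## Statistics

Statistics operate on per-microtubule values by default (per-track and
per-experiment selectable). The battery: each group is screened with the
D'Agostino–Pearson K² omnibus test (implemented from the standard
skewness/kurtosis z transforms; it agrees with independent implementations
to 1e-10 and refuses n < 20 by default). If all groups pass at the gate α
(default 0.05 — the gate level and the correction family are genuinely
open choices; both are configurable), pairwise two-tailed independent
t-tests are used; otherwise Kruskal–Wallis (tie-corrected *H*, χ²
approximation) followed by Conover–Iman or Dunn pairwise tests on pooled
mid-ranks with tie correction, all two-sided. Holm–Bonferroni is applied
across all pairs as one family. Degenerate inputs are defined rather than
fatal: all-identical data give *H* = 0, *p* = 1, and identical groups give
post hoc *p* = 1.

Superplot aggregation reports raw per-unit values, group means at the
requested hierarchy level, and pooled median/quartiles/10–90 percentiles.
Directionality proportions are reported both as pooled-count fractions and
as per-experiment mean ± s.d.; these differ whenever experiments contribute
unequal track counts, which is why both are labeled explicitly.

## The simulator

`simulate_trackset` emulates the assay the analysis assumes:

* landings: Poisson with intensity λ (µm⁻¹ s⁻¹) × microtubule length ×
  landing window, positions uniform along the lattice;
* motion: continuous-time Markov chain over {plus run, minus run, pause}
  with exponential dwells, per-state truncated-normal speeds (CV 0.25 by
  default; the sign never flips within a state), per-state exponential
  detachment, and absorbing truncation at the lattice ends and movie end;
* observation: positions sampled at the frame interval with independent
  Gaussian localization noise σ (default 20 nm). The appearance and
  disappearance times are included as vertices (a tracer spans the full
  visible extent of a line); associations shorter than one frame are
  dropped as unobservable. Identical parameters + seed ⇒ bit-identical
  output.

`trace_tracks` emulates manual tracing: it reduces each sampled track to
the minimal polyline whose vertical (position-at-equal-time) deviation from
the samples stays within ε (default 50 nm ≈ 2.5σ). Feeding raw per-frame
samples to the 25 nm s⁻¹ rule instead would misclassify genuinely static
complexes, because frame-to-frame localization noise alone produces
apparent speeds of hundreds of nm s⁻¹ — the tracing step, not the
classifier, is what absorbs localization noise, exactly as in the manual
workflow.

`true_class` applies the same segmentation rules to the exact noise-free
path and is the recovery target for end-to-end tests: agreement is 100% at
σ = 0 and ≥ 95% at σ = 20 nm for the mixed preset (residual confusion is
almost entirely borderline-static tracks near the 1,000 nm rule).

Presets (`ddh`, `hk`, `ddhk`, `fhf`) encode the study conditions: the
mixed `ddhk` preset uses class weights 83.3% minus / 13.4% plus / 1.6%
static / 1.7% switchers (the observed cocomplex class proportions), and the
`fhf` preset uses the 105 nm / 0.136 s / 500-frame acquisition geometry.
Per-state speeds are not printed anywhere as numbers, so the defaults are
round free choices: 500 nm s⁻¹ for dynein-driven minus runs, 700 nm s⁻¹
for kinesin-driven plus runs; run dwell means (5–6 s) put mean run lengths
in the observed several-thousand-nm range, and landing intensities
(0.04–0.08 µm⁻¹ s⁻¹) give the few-per-µm-per-minute landing rates typical
of these assays.

What the simulator does **not** emulate: force-dependent stepping or
tug-of-war mechanics, photobleaching/blinking, tracing errors other than
noise smoothing, non-uniform landing along the lattice, and microtubule
intersections. Passing recovery tests therefore validates the analysis
logic and its noise robustness, not the biological realism of any preset.

## Problem sizes and numerics

Recovery checks use deliberately moderate sizes — 40 kymographs for
landing-rate recovery (≈ 10⁴ tracks, 3 s.e. criterion), ≈ 2,500 noise-free
tracks for exponential run-length recovery (5% criterion; residual bias
from frame discretization and lattice-end truncation is < 1%), ≈ 2,500
traced noisy tracks for classification recovery (95% criterion), and a
10,000-replicate null for the Kruskal–Wallis type-I error (0.05 ± 0.01).
CSV serialization round-trips floats exactly (`repr` on write, round-trip
float parsing on read). The exact-arithmetic oracles for the post hoc
tests evaluate the literal rank formulas with rational arithmetic before a
single float conversion at the distribution call.
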