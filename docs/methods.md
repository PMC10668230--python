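# Methods

`retmap` simulates the development of the retinocollicular projection under
chemoaffinity, correlated neural activity and synaptic competition, emulates
Fourier-based intrinsic imaging of the result, and reconstructs and scores 2D
retinotopic maps with the Lattice Method.  This note records the model, the
measurement procedures, the parameters that matter, and the design decisions
taken where the problem was genuinely open.

## Coordinate and unit conventions

* Retina: unit-diameter disc; `x` runs nasal (0) to temporal (1), `y` ventral
  to dorsal.  Colliculus: upper half of an ellipse with semi-axes (0.5, 0.6);
  `x` runs rostral (0) to caudal (1), `y` lateral to medial.
* Temporal retina (nasal visual field) maps to rostral colliculus; dorsal
  retina maps medially.  Azimuth phase is expressed in degrees of the scanned
  extent with the nasotemporal convention of the retina (so azimuth
  *decreases* along the rostrocaudal axis in an ordered map); spans default
  to 100° (azimuth) and 80° (elevation).
* The collicular pixel raster is 100×60 over the bounding box with 6 pixel
  widths = 80 µm, i.e. a 1.33 × 0.8 mm structure (hemi-ellipse area
  0.84 mm²).

## Molecular substrate

Retinal EphA follows a normalized exponential ramp `R_A(x) = (e^{kx}−1)/(e^k−1)`
with `k = 2`, scaled so the wild type spans [0, 1].  This is a parametric
stand-in for the measured receptor profiles (the published quantifications
are not reproduced here); any callable or tabulated profile can be supplied.
The EphA3 knock-in adds a fixed augment `DR` to a Bernoulli(0.5) subset of
retinal cells; the heterozygous and homozygous presets are `DR` = 0.37 and
0.74 on the normalized scale.  Collicular ephrinA rises rostral→caudal with
a steeper ramp (`k = 4`); see "Choice of gradient shapes" below.  EphB and
ephrinB are linear on the orthogonal axes (no published shapes to follow).

Cells are placed by rejection sampling against a spatial hash with a hard
minimum spacing (default `0.5·sqrt(area/n)`, well below the jamming density);
10⁴ consecutive failures raise a packing error.

## Development model (multi-contact)

A configuration is a multiset of retina→colliculus contacts with energy

    E = α Σ R_A·C_A − β Σ R_B·C_B
        − (γ_eff/2) Σ_pairs exp(−d_ret/a)·exp(−d_coll/b)
        + (w/2) [ Σ_i (m_i − 1)² + Σ_j (n_j − 1)² ]

with α = 90, β = 135, a = 0.03, b = 0.11 (reference values) and base
activity weight γ = 0.00625.  The chain proposes, with probability ½ each, a
creation sampled uniformly over all cell pairs or a deletion sampled
uniformly over existing contact instances, and accepts with
`1/(1+exp(ΔE/T))`, `T = 1`.  The chain therefore samples a Gibbs
distribution (with a count-dependent combinatorial factor from the proposal
asymmetry) rather than finding a single minimum.

Design decisions:

* **Competition.**  The quadratic per-cell term (soft one-contact-per-cell on
  both sides) is this package's interpretation of the competitive mechanism.
  A per-contact description alone cannot bound the contact count: with the
  product-form chemoaffinity most creations lower the energy without it.
  The weight `w = 5` keeps the count-change barriers (≈ ±w at count
  equilibrium) small enough that contacts remain mobile at T = 1; much
  larger weights freeze the chain, much smaller ones let counts run away.
* **Activity magnitude.**  γ refers to a reference implementation's internal
  correlation functions; with the explicit exponential kernels used here its
  magnitude must be rescaled.  Following the published calibration
  procedure, the multiplier (`activity_scale = 40`, so γ_eff = 0.25) was set
  so that a wild-type virtual injection covering 1% of the retinal area
  innervates ≈1% of the colliculus, and so that the knock-in regime
  structure (separation of the populations at large augments) is preserved.
  Stronger activity (γ_eff ≳ 0.5) drives the two knock-in populations into
  register everywhere and abolishes double maps; see "Known limitations".
* **Developmental schedule.**  γ ramps linearly from 0 to γ_eff over the
  first half of the run (`activity_ramp = 0.5`): chemoaffinity establishes
  the coarse topography before activity-dependent refinement, matching the
  developmental sequence and avoiding an early activity-driven collapse
  onto a locally-smooth but globally unsorted configuration.  With a ramp
  the running energy is logged by full recomputation at the final weight.
* **Pair-sum locality.**  Activity pair sums are truncated at 4·a in retinal
  distance (relative error < e⁻⁴ per pair) using precomputed neighbour
  lists; the collicular kernel is a precomputed dense table, so one MCMC
  step costs a few dozen table lookups.  The incremental energy agrees with
  a full recomputation to ~10⁻¹⁵ relative error.
* Initialization is `n_coll` uniformly random contacts; energies are
  reported unnormalized (only differences matter).

### Choice of gradient shapes

The duplication structure of knock-in maps is controlled by the *retinal*
ramp alone (the caudal-exclusive territory is the set of EphA3− cells with
`R_A < DR`), and with `k = 2` the predicted duplicated field fractions at
DR = 0.22/0.34/0.56 match the reference simulation series closely.  The
*collicular* ramp shape sets where activity can hold the two populations in
register: a steeper ephrinA ramp (`k = 4`) is nearly flat rostrally (fibres
of common retinal origin superpose there) and steep caudally (chemoaffinity
sorting wins), which is the asymmetry that shapes partial double maps.

## One-contact variant

The earlier model version keeps a bijection between equal-sized sheets
(moves exchange the retinal partners of two collicular cells; no competition
term is needed).  Because the hard one-to-one constraint removes the count
entropy of the multi-contact model, this variant is run colder (T = 0.05 in
the regime tests) and with a stronger activity weight (γ_eff = 1); it
reproduces its three regimes: single ordered maps at DR = 0, interleaved
("blotchy") maps at intermediate augments, and fully double maps at large
augments.

## Fourier-imaging emulation

A bar of width 2% of the retinal extent sweeps one axis during the first 80%
of each cycle (the off-screen remainder removes the phase wrap-around
ambiguity).  Retinal cells fire Poisson spikes (30/frame under the bar, 0.2
baseline); collicular drive is the contact-weighted spike sum accumulated on
the pixel raster and passed through a centre-surround interaction: Gaussian
excitation (σ = 0.05 normalized), minus 3× the *scan-mean* drive smoothed at
the surround scale (σ = 0.15), rectified at zero.  A temporally integrating
surround suppresses weakly driven territory without mixing neighbouring
phase information into the response (an instantaneous subtractive surround
corrupts recovered phases by tens of degrees).  Scan parameters (5 cycles ×
72 frames) are exposed in `ImagingParams`; the published protocol does not
state them.  Per pixel, the Fourier coefficient at the repetition frequency
gives phase (field position) and amplitude; noiseless phases are recovered
to well under 1°.

The per-pixel *fluctuation statistic* is the standard deviation of the
reported 2D field position over the 3×3 neighbourhood (channels pooled as
`sqrt(var_az + var_el)`, in degrees).  It is the quantity the reliability
filter thresholds; the neighbourhood size is configurable.

## Filtering

1. Keep the `k` most active pixels by elevational amplitude (default 10⁴ —
   on this raster, every responsive pixel; ties break in raster order).
2. Fit an amplitude-weighted second-moment ellipse to the active pixels and
   reject pixels outside it.  Weights are capped at the median amplitude
   (response strength varies considerably across the structure, and uncapped
   weighting drags the fit toward the strongest corner).  The inclusion
   boundary is the 97.5% amplitude quantile of Mahalanobis radius, floored
   at the uniform-filled-ellipse boundary (m² = 4) with a 30% margin; a
   re-filtered map carries its ROI forward, so filtering is idempotent.
3. Reject pixels whose fluctuation statistic exceeds 3× the wild-type
   baseline (median statistic of a designated WT map).  A baseline must be
   supplied for knock-in maps; wild-type maps may use their own.

## Lattice Method

Virtual electrodes are placed one by one at random eligible pixel centres at
spacing Δ = 6 pixel widths = 80 µm; each must lie ≥ 0.9Δ from all others and
≤ 1.1Δ from at least one earlier electrode (the literal "Δ ± 10% from all
existing electrodes" is unsatisfiable beyond a few electrodes; this reading
keeps the lattice connected and even).  Random sequential placement jams at
≈110–130 electrodes on this 0.84 mm² raster (the experimental counts of
150–200 refer to ≈1 mm² at somewhat denser packing).  Each electrode's
visual node is the mean reported field position of eligible pixels within
Δ/2; electrodes with none are dropped with their partner.  Collicular nodes
are Delaunay-triangulated; an edge is flagged when its visual-field segment
properly crosses another's (shared endpoints excluded).  The largest ordered
submap is extracted greedily: repeatedly remove the node with the most
flagged incident edges (ties: larger summed crossing count, then lower id),
recomputing flags on the induced edge set without re-triangulating (new
edges across holes would connect non-adjacent regions); on ≤16-node
instances the greedy result is within one node of the exhaustive optimum.

Partitioning: the dividing line between two projection areas is the straight
fit to a least-cost path from the lateral to the medial raster edge over a
cost field in which reliability-rejected pixels are cheap — the automated
equivalent of the hand-drawn line through the rejected band.  A user line
overrides; an equal-halves split (at the median rostrocaudal position of
eligible pixels) is the wild-type convention and the fallback when no band
separates the region.  Partmaps are built independently per side.

## Metrics

* **Map Quality**: percent of nodes retained in the largest ordered submap
  (raw float retained; report rounded).
* **Polarity**: percent of edges whose field-axis and collicular-axis
  components agree in sign with the expected orientation, after rotating
  field coordinates by 20° (the oblique projection of the nasotemporal axis
  in wild-type maps); 100 perfect, 50 random, 0 reversed; zero-component
  edges excluded.
* **Magnification**: median per-edge ratio |field component (°)| /
  |collicular component (mm)|; edges with collicular component below 10% of
  Δ are excluded (the ratio diverges on near-degenerate edges).  The median
  is this package's aggregator choice.
* **VFD**: field footprints of the two partmaps are alpha shapes of their
  visual nodes (triangles kept below 2× the upper-quartile node spacing;
  convex hull under 10 nodes), buffered by half the median node spacing
  (node centres sample the interior of the mapped region, so the raw shape
  underestimates it by about half a spacing all round);
  VFD = 100·area(∩)/area(∪).  On synthetic ground truth this recovers a
  30% duplication to within ±3 points and reports ≈78 for a fully double
  map — the boundary loss the full-scale reference simulations also show
  (they print 76 for a completely double map).
* **1D profiles**: eligible pixels within 2.5° of a target elevation define
  a total-least-squares track on the colliculus; azimuth of eligible pixels
  within one pixel width of the track is reported against arc length.

## Synthetic ground-truth maps

`generate_phase_map` builds single, partial-double (parameterized
duplication fraction) and fully-double phase maps over the same raster:
the rostral area maps the whole field, the caudal area the duplicated
(temporal-field) fraction, and the strip between them flips per pixel
between the two competing positions (Bernoulli ½) — the unstable averaging
the reliability filter targets — plus Gaussian phase noise (default 2°).
Elevation is normalized by the local height of the hemi-ellipse, so
iso-elevation lines follow the curved outline as in real maps.  What these
fixtures do not emulate: amplitude falloff across the structure, vascular
artefacts, and scan miscalibration; tests passing on them validate the
analysis chain, not the biology of real data.

## Desk-scale protocol and problem sizes

The reference reduced protocol is 2000+2000 cells with 2×10⁷ steps.  This
package's desk-scale protocol uses 1000+1000 cells with 10⁷ steps for the
headline runs (5 seeds per condition) and 500+500 cells with 4×10⁶ steps for
the augment sweep (10 runs per value); steps scale as ≈5 proposals per
cell pair, matching the reference protocol's density.  The acceptance
script (`scripts/acceptance.py`) runs exactly this protocol; the test suite
uses the same sizes for the headline runs.

## Known limitations

* At the calibrated operating point the model reproduces single wild-type
  maps, the injection calibration, the onset of irregularities at small
  augments, high partmap order, and the separation of the populations —
  but the *measured* visual-field duplication at DR = 0.56 stays far below
  the reference series (a few percent rather than ~74): with these kernel
  stand-ins the chain settles into either a globally E-sorted interleaved
  arrangement or (at stronger activity) a fully registered compressed
  single map, and the two-complete-submap configuration that produces large
  duplication is not stable anywhere in the explored (γ, w, T, gradient
  shape) space.  Stability tests initialized *in* the double state confirm
  it decays.  Reproducing it likely requires the reference implementation's
  specific competition normalization.
* Polarity on one-contact (bijective) anatomical lattices saturates near
  88% at desk scale — each visual node averages only 2–3 contacts; the
  imaging emulation (which averages many more) restores >90%.
* The critical-augment estimate is noisy at n = 500 (half-split VFD medians
  move by ±1–2 points between seed sets), so the detected onset can move by
  one grid step between runs.
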