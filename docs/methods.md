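# Methods

## Coordinate model

All machine motion is absolute, in millimetres. A plate is a rectangular
grid of circular wells; row A is the row nearest the machine origin along
+y, columns advance along +x, and `swap_xy` exchanges the roles of the two
pitch axes for plates mounted rotated by 90°. Pattern mathematics happens
in a *well-local* frame (origin at the well center, axes parallel to the
machine axes); placement adds the well-center translation
`(a1_x + (col−1)·px, a1_y + row·py)`.

The bundled presets use standard SLAS plate geometry (127.76 × 85.48 mm
footprint; 6-well pitch 39.12 mm and diameter 34.6 mm, 24-well pitch
19.3 mm and diameter 15.6 mm, etc.). Their A1 machine coordinates assume
the footprint corner clamped at machine (40, 30) and exist to be replaced
by bench calibration — determining the true x/y/z offsets is a physical
procedure, not computation, and is out of scope here
(`PlateSpec.calibrated` applies the measured offsets).

## Safe region and patterns

Every pattern is confined to the safe disk of radius
`r_safe = well_diameter/2 − tip_offset`. The tip offset (default 2 mm)
is the wall-safety margin of the validated protocol.

* **Mesh** — `L` parallel chords at perpendicular offsets
  `o_i = (i − (L−1)/2)·d`, symmetric about the center (for even `L` no
  line passes through the center). Each chord spans the full safe circle,
  endpoints at `±√(r_safe² − o_i²)`. Lines are ordered serpentine to
  minimise travel. Offsets falling on or outside the safe circle are an
  error by default; dropping them is opt-in (`strict=False`), because
  silently changing geometry would corrupt replicate comparability.
* **Grid** — the mesh plus its 90° rotation; `L` lines each way cut the
  disk into `(L+1)²` curvilinear islands when every pairwise crossing
  falls inside the circle.
* **Circles** — concentric rings `r_k = inner + k·step ≤ r_safe`,
  innermost first. Rings are flattened to regular polygons targeting a
  sagitta of *half* the flattening tolerance, which keeps both the radial
  deviation and the inscribed-polygon perimeter deficit inside the
  tolerance class (at `tol = 0.05 mm`, `r = 10 mm` the perimeter is
  within 0.1% of `2πr`). Default `inner = step = 1.6 mm` mirrors the mesh
  spacing; the choice is ours and configurable.
* **SVG** — subpaths of `path` (M/L/H/V/C/Q/Z), `rect`, `line`,
  `polyline`, `polygon`, `circle`, `ellipse`, with translate/scale
  transforms. Béziers are subdivided (de Casteljau) until the control
  polygon is within the tolerance of the chord, which bounds the true
  curve deviation via the convex hull. Elliptical arcs, text and other
  elements are rejected by name rather than approximated — users can
  convert them in Inkscape. Fitting scales the drawing so the
  circumradius of its bounding box equals `svg_scale/100 · r_safe` and
  centers it on the well: containment is guaranteed for any drawing, at
  the price of under-filling very elongated ones (an inscribed-shape fit
  would fill more but can escape the disk for concave drawings). SVG's
  y axis points down, so y is flipped on import (configurable).

Default flattening tolerance is 0.05 mm, an order of magnitude below the
narrowest tip contact width (0.7 mm): flattening error is invisible at
the scale of the physical scratch.

## G-code dialect

Marlin-flavoured subset: `G21`, `G90`, `G28`, a configurable leveling
token (default `G29`, emitted once per program when auto-leveling is on),
`G0` rapids at the travel feed, `G1` scratch moves at the scratch feed,
`G4 S<sec>` dwells, `;` comments. Feed words are repeated on every motion
line and coordinates are fixed 3-decimal mm, so programs are byte-stable
for identical inputs. The header echoes every parameter (including the
two z heights), making each file self-describing for the parser.

Per well: lift to `travel_z`, rapid to the first point, plunge to
`scratch_z`, traverse each polyline `scratch_cycles` times alternating
direction (back and forth, not re-rapiding to the start), lift between
polylines. Scratch cycles default to 2 and feeds to 6000 mm/min
(100 mm/s), the protocol's validated values. The wash routine (travel to
the station, plunge, dwell ≥ 30 s, lift) can be emitted before and/or
after the wells; a station inside the plate footprint is rejected as a
collision risk. The station position and routine shape are this package's
design.

Well-local coordinates are quantized to the 1 µm output grid *toward the
well center* before formatting: per-axis rounding toward zero never
increases a point's distance from the center, so quantization can never
push a path across the safe circle. Consequently the parsed minimum wall
clearance is ≥ `tip_offset` always, and equals it exactly when the
touching coordinates are representable at 3 decimals (true for all
bundled presets).

The parser carries modal state (position, feed), classifies horizontal
motion at `scratch_z` under a well label as scratch, motion inside a wash
block as wash, `G4` as dwell, everything else as travel; `G91` (relative
mode) and unknown commands are errors with line numbers. A *scratch
block* is a maximal run of consecutive scratch segments in one well (one
plunge); traversal counts divide a block's segment count by its number of
distinct undirected segments; distinct-line counting canonicalizes each
segment's infinite line (unit direction with a sign convention plus
signed origin distance, rounded at 10⁻⁶) so collinear duplicate
traversals merge.

## Swept-footprint raster

A pixel is wound iff its center lies within `contact_width/2` of any
scratch segment (union of stadia). The grid is *cell-centered*: pixel
centers sit at half-integer multiples of the pixel size about the well
center. This makes the raster exactly symmetric under 180° rotation and
— unlike a node-centered grid — keeps stadium boundaries with "round"
radii (e.g. 0.4 mm at 10 µm pixels) from slicing through entire rows of
pixel centers, so the midpoint-rule area estimate is within 0.5% of the
analytic union-of-stadia area at the default 10 µm pixels. The pixel size
must not exceed half the contact width (undersampling is an error). The
nominal tip widths are used by default; real scratches run wider because
the tip vibrates and pushes cells ahead of it, so the effective width is
an explicit `TipSpec` parameter, never a hidden calibration.

## Quantification

Stations are pixel columns perpendicular to the scratch axis (given as
x/y/angle, or estimated as the wound's principal axis). Width at a
station is wound-pixel count × pixel size; columns with multiple runs sum
them. Stations within `end_cap_mm` of the wound's axial extremes are
excluded so stadium end caps do not bias the statistics (pass
`contact_width/2` for simulated wounds); area counts all wound pixels.
Straightness is the SD of the width profile. All replicate statistics use
the sample (n−1) SD — whether published CVs use population or sample SD
is generally unstated; we fix sample SD. The relative difference
normalizes by the larger mean, the convention under which the two printer
mean widths 925.7 and 971.2 µm give 4.68% (the smaller-denominator
convention would give 4.92%). `wound_metrics` is specified for straight
scratches only; for complex shapes only the area is meaningful.

## Synthetic wound masks

The fixture generator emulates imaged scratches without any microscopy:
a straight gap whose two edges are independently displaced by a
stationary Gaussian process (white noise convolved with a Gaussian kernel
of the correlation length, demeaned, then rescaled so the realized
within-scratch SD equals `edge_sd` exactly), and whose per-replicate mean
width is drawn around `base_width` with SD `width_sd_percent`. Defaults:
900 µm base width, 500 µm correlation length. Two shipped regimes,
`ROBOTIC_JITTER` (edge 15 µm, width 1.6%) and `MANUAL_JITTER` (edge
80 µm, width 16%), reproduce the observed order-of-magnitude CV contrast
between plotter-driven and hand scratching; measured through the full
quantification path they come out near 1.7% and 15% for 24 replicates.

What the generator does **not** model: cell-scale texture, frayed or
asymmetric wound edges from cell sheet tearing, debris and reattachment,
illumination artifacts, or segmentation error — passing tests show the
geometry and statistics pipeline is correct, not that segmentation of
real micrographs would be. Masks enter this package already binary.

## Problem sizes and determinism

Tests and the acceptance script run on one CPU in seconds: raster tests
use 10–25 µm pixels on single-well frames (≤ ~1.5k² pixels), replicate
statistics use 20–30 synthetic masks at 20 µm, and the containment fuzz
covers 1000 random pattern specs. Every stochastic component takes an
explicit integer seed (`numpy.random.default_rng`); identical inputs give
byte-identical G-code and bit-identical masks.

## Known limitations

* Calibration offsets, spring-probe travel and leveling mechanics are
  hardware concerns; the package only emits the leveling trigger and
  exposes `scratch_z` as a single number.
* No serial transmission to printers; programs are files.
* The effective (realized) scratch width is a user-supplied parameter;
  no model links speed, tip and cell line to realized width.
* `wound_metrics` assumes one straight scratch per analysis window;
  grids and drawings are quantified by area only.
* Free-angle mesh rotations are not offered (only 0°/90°), matching the
  workflow this package automates.
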