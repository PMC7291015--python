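# Methods

`digispindle` implements a "digital spindle" analysis for microtubule growth
dynamics in dividing cells: EB1–GFP comets — fluorescent marks on growing
microtubule plus ends — are followed in 3D+t light-sheet volumes, linked into
growth trajectories, mapped into a spindle-fixed reference frame, and
classified by growth speed, spherical zone of origin, and travel angle
against the spindle axis. Because the source imaging data are not public,
the package pairs the analysis chain with a ground-truth simulator that
reproduces the acquisition's statistical structure, so every stage can be
validated by parameter recovery.

## Coordinate and unit conventions

All distances are physical micrometres, times seconds, angles degrees.
Coordinates are right-handed with z the optical axis. Volume arrays are
indexed `(z, y, x)` in voxel order; the position `(0, 0, 0)` is the centre of
the first voxel, so voxel `i` along an axis sits at `i * pitch`. This gives
unambiguous round-tripping between volumes and coordinate tables.

## Acquisition model

The default acquisition mirrors a dithered-mode lattice light-sheet
time-lapse: 75 volumes at 0.755 s intervals (56.625 s), with a separable
Gaussian PSF of 230 nm lateral / 370 nm axial FWHM. Default voxel pitch is
0.104 µm laterally and 0.2 µm axially over a 32 × 22 × 22 µm field of view;
the paper-scale acceptance run coarsens this to 0.15/0.3 µm to keep a
75-frame full-cell simulation tractable on one core — a resolution the
detector tolerates because only counts, not sub-voxel localisation, matter
there.

## Simulator

**Spindle geometry.** Two centrosomes at distance d (metaphase default
10 µm; prometaphase 8, anaphase 12 with slow pole separation, telophase 14 —
package defaults, not measured values) define the spindle axis. The whole
spindle drifts: constant-velocity translation of the midpoint
(0.02 µm/s default) and rotation about a random fixed axis through the
midpoint (0.2°/s default), both seeded and optionally pinned to a chosen
axis. Comets are *rigid with the spindle*: trajectories are generated in the
spindle's own frame and mapped to the lab through the per-frame pose, so
drift is imprinted on the data exactly as drift correction must later remove
it. The trajectory's recorded true speed is its spindle-frame speed;
whole-spindle motion is not comet motion.

**Trajectories.** Births follow a Poisson process in time. Each birth picks
a pole (1:1), a spherical zone around it (default weights decline from the
pole, zone 1 = 0.20 down to zone 10 = 0.03), a start radius uniform within
the zone shell, a constant speed from `Normal(zone mean, sd)` clipped to
[0, 1] µm/s (default means decline linearly 0.55 → 0.35 µm/s with
sd = 0.1), a direction from a von Mises–Fisher law about the outward axis
direction (concentration 1.0 by default; 0 gives isotropic growth), and an
exponential lifetime (mean 8 s). Motion is straight-line at constant speed —
the near-constant growth regime of EB1 comets; trajectories truncate at the
final frame and the field-of-view boundary. Desk scale (birth rate 5.5/s,
≈300 trajectories/cell) keeps tests fast; paper scale (70/s) reproduces the
published per-cell magnitudes (>2,000 trajectories, >10,000 comet
observations over 75 frames).

**Rendering.** Each comet is a tip-anchored emitter whose intensity decays
as `exp(-decay · s / L)` over a tail of length L = 500 nm (decay 3) behind
the tip along the reversed velocity; the 25 nm cross-section is folded into
the PSF in quadrature. Samples along the tail are splatted as normalised
Gaussians evaluated at voxel centres, so the noise-free photon budget per
comet equals `peak_signal` (default 1000 photons) times the bleaching factor
`exp(-rate · t)` (default 0.005/s, applied to signal only — the simplest
defensible model). Centrosomes render as 5×-brighter PSF-sized foci.
Noise is Poisson on signal plus uniform background (10 photons/voxel),
followed by zero-mean Gaussian read noise (sd 1.5) clamped at zero.
A stationary emitter therefore measures the configured PSF: 233.7 nm
lateral / 371.6 nm axial FWHM at 0.05 µm pitch (the small excess over
230/370 is the comet cross-section plus voxel sampling).

A consequence of this physically motivated comet model: the *blurred
intensity maximum sits ≈ 0.1 µm behind the true tip* (exponential tail of
decay length ≈ 167 nm under a 230 nm PSF). Any argmax-style detector
inherits this offset. It is constant along a trajectory, so step lengths,
speeds and travel angles are unaffected; start positions shift by ≲ 1/5 of
a zone shell.

## Detection

Comets are enhanced with a scale-normalised, sign-flipped
Laplacian-of-Gaussian whose per-axis scales are the expected comet FWHMs in
voxel units (anisotropy-aware; ratios above 10 are rejected with advice to
resample). The volume's DC level is removed first so the truncated kernel is
exactly offset-free. Candidates are strict local maxima above a robust
threshold (median + k·1.4826·MAD of the response, k = 8 — stable under
bleaching-induced decay; an absolute threshold is available), non-maximum
suppressed within 0.5 µm, and refined per axis by a quadratic through the
three response samples (offsets clipped to ±½ voxel). Localisation bias on
a noise-free point source is below half a voxel per axis.

Because the centrosome foci are several-fold brighter than comets, they both
appear as spurious detections and mask the local maxima of comets within
≈0.8 µm. The pipeline therefore performs *pole suppression*: at the known
centrosome positions (required downstream for registration in any case) a
Gaussian with the PSF sigmas plus a local constant is fitted by linear least
squares and subtracted, and residual detections within 0.3 µm of a pole are
discarded. With it, frame-level recall/precision against ground truth at a
0.3 µm matching radius are ≥ 0.95 / ≈ 1.0 at default desk density.

## Linking

Frame pairs are linked by a globally optimal one-to-one assignment on the
gated matrix of squared displacements, with a birth/death cost of `gate²`
per unmatched detection (solved by the Hungarian algorithm); links beyond
the gate never occur, and a link is dropped whenever terminating plus
starting is globally cheaper. The default gate is `1 µm/s × interval +
2 × lateral pitch` — the top of the comet speed scale plus localisation
slack. No gap closing by default (comet disappearance is treated as
catastrophe); optional one-frame gap closing interpolates the missing point
at the midpoint. Tracks shorter than 4 points are discarded (a
testability default — no filter is prescribed by the source analysis), and
ids are assigned in frame-then-position order for reproducibility.

Mean travel speed is path length over elapsed time — the per-step growth
rate semantics of EB1 analysis; net-displacement speed is emitted alongside
it in the summary table.

## Registration (drift correction)

Each frame is mapped by the rigid transform placing the centrosome midpoint
at the origin and the pole-1 → pole-2 direction on +x (minimal rotation,
axis = cross product; an antiparallel axis uses a deterministic 180° turn
about +z). Two centrosomes leave roll about the spindle axis undetermined;
it is fixed per frame by the closed-form roll that minimises the rotation
relative to the previous registered frame (first frame: minimal rotation
from the lab). This keeps registered trajectories temporally smooth; a pure
rotation about an axis perpendicular to the spindle axis is removed exactly
(verified to 1e-6 µm against a drift-free twin simulation, with isometry
and round-trip invariants at 1e-9). Pole identity is fixed at frame 0 and
propagated by proximity to prevent axis flips. Cells of the same phase are
merged by pooling registered tracks with cell provenance retained; optional
normalisation divides each cell's coordinates by its mean intercentrosomal
distance (off by default, since whether the original analysis rescaled
spindle length before merging is unknown).

## Classification

Speed classes are half-open `[k/10, (k+1)/10)` µm/s bins over 0–1 µm/s
(the top bin closed), ten by default; out-of-range tracks are reported, not
dropped. Zones are ten concentric shells of equal thickness covering a
sphere of radius d around each centrosome; a track belongs to the shell of
its start point around the *nearer* pole (the spheres overlap mid-spindle
because each radius equals d; exact ties go to pole 1), computed as
`ceil(n·r/d)` with r = 0 → zone 1 and r > d → "outside". The registered
frame with time-averaged d is used; callers needing per-frame d can build a
partition from any frame's d. Travel angle is the arccos of the clamped
normalised dot product between the net displacement and the pole→opposite
pole direction (0–180°, distinguishing poleward from anti-poleward growth);
the 0–90° folding against the undirected axis is emitted as a derived
column since either convention may be wanted. Zero-displacement tracks are
flagged undefined and excluded from summaries. Per-zone summaries report
counts, mean angle, circular sd, and a 10° histogram. Random subsampling
(`round(fraction · n)` without replacement, seed-stable) supports the
13%/20% display-thinning used for average models.

## Determinism and seeding

One global seed derives independent substreams (geometry, trajectories,
rendering noise, subsampling) via `numpy` seed sequences, so identical
configurations are bit-identical — including CSV outputs, which are written
with a fixed column order and float format.

## What the simulator does and does not show

Passing parameter-recovery tests demonstrates that the chain is unbiased
under the simulator's assumptions: straight constant-speed growth, Gaussian
PSF, Poisson+read noise, isolated or mildly crowded comets, and exactly
known centrosome positions. Real data add curved trajectories, motion blur,
uneven background, spherical aberration, detection on deconvolved volumes,
and centrosome positions that must themselves be tracked — none of which are
modelled. Accuracy numbers here are therefore upper bounds on real-data
performance, not estimates of it.

## Problem sizes

Desk-scale runs (defaults) use ≈300 trajectories per 75-frame cell and a
0.104/0.2 µm grid; the paper-scale acceptance run uses the published
trajectory density on a 0.15/0.3 µm grid. These sizes were chosen so a full
simulation-analysis round trip completes in minutes on a single core.
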