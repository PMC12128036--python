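# Methods

This note records the models implemented in `micellekit`, the defaults and
why they hold, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Units and conventions

All internal lengths are angstrom (GRO files, in nm, are converted at the
boundary), times are ns, masses amu. Boxes are orthorhombic; triclinic input
is rejected explicitly. `minimum_image_displacement(p, q)` returns the
wrapped `q − p` with every component in [−L/2, L/2).

## Aggregate detection

Single-linkage clustering over tail-bead contacts: beads i, j are in contact
when their minimum-image distance is ≤ r_cut, and molecules are merged by
transitive closure. The cutoff is r_cut = (5/4)·σ_LJ of the *smallest* tail
bead present (σ taken from the Martini 3 size-class table R/S/T =
4.70/4.10/3.40 Å, overridable per bead), which respects the different
equilibrium tail spacings of models at different mapping resolutions.
Contacts are found with a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`); the test suite asserts bit-identical partitions against an
all-pairs union-find oracle. The partition always covers every surfactant —
monomers are singleton clusters — and the minimum aggregation number
(default 5) filters reporting only, so normalized aggregation numbers sum
to 1 per frame.

Unwrapping assigns one lattice offset per molecule by BFS over contact
edges, each edge taken at its minimum image; if BFS revisits a molecule
with a conflicting offset the cluster is connected to its own periodic
image and is flagged `percolating` (lamellae). Percolating aggregates keep
their membership but are refused by the shape metrics and skipped (counted)
by the surface pipeline.

## Shape metrics

Each surfactant enters as a single point: the mass-weighted mean of its
beads, carrying the summed bead mass (a `bead_resolved=True` flag switches
to per-bead points). R_g is the mass-weighted root-mean-square displacement
from the center of mass. The inertia tensor's ascending eigenvalues
(A, B, C) are inverted through the uniform solid ellipsoid relations
a² = 5(B+C−A)/(2M) (and cyclic) to ordered semiaxes; moments violating the
triangle conditions (e.g. quasi-linear configurations) raise a dedicated
error and the aggregate is reported with NaN axes and class `degenerate`.

Classification thresholds: `sphere_tol = 0.15` (an eccentricity below which
two axes count as equal) and `split_tol = 0.10` (the maximum e_ac − e_ab
separation still counted as prolate). These are configurable; the defaults
were chosen to separate the four canonical regions of the CPE plane while
tolerating the finite-sample eccentricity of a few hundred points
(e ≈ n^(−1/4), about 0.05–0.09 at n ≈ 200–400). Note that a hard boundary
at e_ac = sphere_tol means borderline spherical/oblate cases near that line
are classification-noise sensitive by construction.

Because the solid-ellipsoid inversion is applied to aggregates that are
really head-shells with tail-filled cores, the recovered semiaxes are
systematically ~10–20% smaller than the head-shell semiaxes; the axis
*ratios*, hence the CPE, are preserved whenever the mass distribution is a
radial scaling of the shell (exact for the synthetic generators, approximate
for thermal aggregates).

`experimental_rg(c, ε) = (c/√5)·√(1+2ε²)` converts scattering-derived
oblate-model parameters (minor semiaxis c, axis ratio ε) into an R_g for
comparison with simulation; with c = 12.57 Å and ε = 1.22 it gives 11.21 Å.

## Willard–Chandler surfaces

The density is an *unnormalized* sum of isotropic Gaussians
exp(−|Δ|²/2h²) over all beads of the aggregate (heads and tails; never
solvent or ions), evaluated on a regular grid. "Bandwidth" is interpreted
as the Gaussian standard deviation h (standard KDE usage); default
h = 4.0 Å, grid spacing 2.0 Å (the actual spacing divides each box edge
exactly), isovalue ρ_max/3 with ρ_max the grid maximum — normalization
cancels in the ratio. Kernels are truncated at 4h; the omitted mass is
~e⁻⁸ per kernel, which bounds the field error at ~0.5% at nodes holding a
tenth of the peak density (measured against an untruncated double loop; 5h
brings it below 0.1%). Two periodicity modes exist: `supercell` evaluates
every bead through its 3×3×3 replicas (replicas beyond the truncation
radius of the box are skipped), `minimum_image` through the nearest image.
For a compact aggregate away from the boundary the two are identical to
machine precision, which is why the supercell-vs-minimum-image volume
excess on the synthetic micelle battery evaluates to 0.0%.

Marching cubes (scikit-image, Lewiner) runs on the field padded by one
periodically wrapped layer, so the grid covers [0, L] exactly once; seam
vertices (coordinate 0 vs L) are merged by quantized-key identification.
The merged mesh is only *topologically* embedded — triangle areas are
therefore computed with per-face minimum-image edges, and enclosed volumes
by first unwrapping each component (BFS over mesh edges, again minimum
image) and then summing signed tetrahedra. Face orientation follows the
descending density gradient (outward from the dense phase), so an outer
vesicle surface counts positive and the inner surface, whose normals point
into the lumen, negative: the default "volume" is the *material* shell
volume, with the lumen-inclusive outer-component volume also available per
component. Components that wind around the box (lamellar sheets) have no
embedded volume and report NaN; their area is still exact. A component with
edges not shared by exactly two faces is open; volume requests on open
meshes raise with the boundary-edge count.

`aggregate_surface` recenters the cloud by circular mean before gridding
(making area/volume exactly invariant under periodic translation of the
input) and, by default, evaluates the field on a snug subgrid around the
aggregate (padded by the truncation radius) — a large speedup in dilute
boxes with no effect beyond grid alignment. Whole-box fields remain
available through `gaussian_density_grid` and are what the acceptance
script uses for the mode comparison.

Grid-maximum sensitivity: ρ_max is sampled on the grid, so translating a
*single* sharp Gaussian by a non-grid-multiple shifts the isovalue by up to
~9%. Real aggregates (hundreds of beads) are insensitive; the recentring
in `aggregate_surface` removes the effect entirely.

## Bilayer geometry

The lamellar surface yields two leaflet components (split by mesh
connectivity; the two largest by area are used, extras — e.g. a coexisting
micelle — trigger a recorded warning). Thickness is the pooled
nearest-vertex minimum-image distance from each surface to the other
(symmetric under swapping); area per headgroup is (A_upper + A_lower)/N.
The bilayer pipeline analyses t > 30 ns by default (the pre-equilibration
of the box area is discarded) and skips-and-counts frames whose surface is
not two-leaflet.

## Equilibration (MSER + ADF)

Per-aggregate properties (SA:V, area/N, volume/N, R_g, N) are reduced to
one mean per time step over aggregates with N ≥ 5; empty time steps are
dropped with a log record. MSE(k) is evaluated for k = 0..⌊3n/4⌋ via suffix
sums (asserted exactly equal to the direct two-pass evaluation); ties break
to the smallest k; the ⌊3n/4⌋ cap keeps the (n−k)⁻² prefactor from
degenerating as k → n. The truncated segment's mean and standard deviation
are the equilibrium estimates, and the *system* convergence time is the
maximum truncation time over the property set.

Stationarity uses the augmented Dickey–Fuller test (statsmodels) with a
constant regression term, AIC lag selection up to ⌊(n−1)^{1/3}⌋, and the
verdict "stationary" when the statistic is below the critical value at the
requested confidence (default 99%). A zero-variance segment is trivially
stationary (flagged degenerate, warned). MSER is applied to the raw series;
an optional batching (MSER-m) is deliberately not implemented — unbatched
truncation plus the ADF check covers the use case.

Binned reporting defaults to 100 ns bins with a seeded percentile bootstrap
(1000 resamples) for 95% confidence intervals; property extraction assumes
the 2 ns sampling interval carried by the frame times.

## Synthetic structures: what they emulate, and what a green test means

The generators produce *geometric idealizations* of self-assembled states —
head beads on the structure's outer surface, 7-bead AOT-like molecules
(1 R + 2 S head beads, 2 × 2-bead splayed tails, smallest tail bead T so
the default cutoff is 4.250 Å), tails running inward — plus isotropic
Gaussian positional noise. They emulate geometry and topology, not
thermodynamics: no solvent, no thermal conformational ensemble, no
polydispersity within a structure. A green recovery test establishes that
the *analysis* is correct on a structure whose ground truth is known; it
says nothing about force-field realism.

Layout choices that matter (all deliberate, all needed for ground-truth
recovery at realistic aggregation numbers):

- **Low-discrepancy head placement.** Ellipsoid heads sit at latitudes
  drawn from the inverse CDF of the azimuth-averaged area-element marginal
  with golden-angle azimuths (seeded phase). Independent uniform/rejection
  sampling would give inertia-eigenvalue noise ~n^(−1/2), i.e. apparent
  eccentricities ~0.3 at n ≈ 300 — a "sphere" fixture would classify as
  triaxial no matter how correct the analysis. Residual azimuthal
  area-weighting is ignored; the induced CPE bias is ≤ 0.05 for aspect
  ratios ≤ 2.5.
- **Tails fill the core.** Micelle chains run toward the aggregate center,
  reaching 3/4 of the way in; bilayer leaflet chains span 3/4 of the
  bilayer thickness, so opposing leaflets interdigitate — the regime of
  double-tailed surfactants like AOT. The doubled core density puts the
  ρ_max/3 isosurface at the head planes, making the generator's declared
  thickness the head-to-head distance the surface method measures.
- **Splayed tails.** The two tails of each molecule splay ±5 Å laterally at
  the tip (equidistributed azimuths; fixed ±x in lamellae so each bead
  depth layer remains a void-free lattice, with the lower leaflet staggered
  half a cell in y). The splay provides the lateral tail-tail contacts that
  make a quasi-crystalline fixture cluster like the liquid aggregate it
  stands in for; without it, molecules 7 Å apart would never touch at a
  4.25 Å cutoff.

Default surfactant density: 55 Å² per headgroup for curved structures,
50 Å² for lamellae (the flat-bilayer reference value; ground-truth area per
headgroup is then 2·Lx·Ly/N exactly). Dispersed systems place components
at random centers with clearance (sum of extents + 15 Å) and record the
ground-truth partition; placement failure after the retry budget raises.

## Degenerate inputs and tie-breaks

- Single-surfactant aggregates: R_g = 0, shape class `degenerate`.
- Collinear/coplanar mass distributions: warning, moments still returned;
  the semiaxis inversion then raises its triangle-condition error.
- Constant property series: MSE ≡ 0, k* = 0 by the smallest-k tie-break;
  ADF degenerate-stationary with a warning.
- Clustering with 2·r_cut ≥ min box length is refused (minimum-image
  ambiguity); KDE truncation spheres larger than half the box warn.
- Contact distances exactly equal to r_cut count as contacts (≤, matching
  the k-d tree and the oracle).

## Known limitations

- Orthorhombic boxes only; no triclinic cells, no velocities.
- Aggregate identity is per-frame; fusion/fission lineage across frames is
  out of scope.
- The solid-ellipsoid inversion reports effective (mass-distribution)
  semiaxes, not head-shell dimensions; compare CPEs, not raw axes, across
  methods.
- Binary trajectory formats are supported only through the adapter contract
  (any iterator of `Frame`s); the bundled readers are GRO and the JSON
  container.
- `minimum_image` KDE mode double-counts if the truncation sphere exceeds
  half the box (warned); use supercell mode for very small boxes.
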