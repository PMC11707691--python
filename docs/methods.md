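# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `serialindex`, in the order data flows through the
package.

## Geometry and the Ewald construction

A still diffraction image is modelled with a single flat panel normal to
the beam: beam along +z, detector plane at z = camera length, fast scan →
+x, slow scan → +y, 0-based pixel indices, and a pixel located at its
centre. Internal units are Å for wavelength, Å⁻¹ for reciprocal vectors
and mm for laboratory coordinates; conversions happen only at file I/O.

A peak at laboratory position **p** scatters along ŝ = **p**/|**p**| and
maps to the scattering vector **q** = (ŝ − ẑ)/λ, using the nominal
wavelength and zero wavelength spread. Every mapped peak therefore
satisfies |**q** + ẑ/λ| = 1/λ exactly (to rounding), which the tests
assert at 10⁻⁹ relative.

Laboratory-frame mask rectangles are converted **once per geometry** into
pixel-index ranges (membership by pixel centre, with a 10⁻⁹ mm slack so
exact boundaries are kept); the per-frame mask work is then a sentinel
comparison (a pixel value of 65535 marks an unusable pixel) plus
precomputed rectangles. Binning sums n×n squares (n ∈ {1..4}), with edge
blocks partial, the output masked wherever any member pixel was masked,
and counts conserved on unmasked input.

## Peak search

The search follows the peakfinder8 idea: the background of a still varies
much faster radially than circumferentially, so each pixel is thresholded
against statistics of its own thin annulus (width 1 px, floor binning)
around the beam centre. The pixel→annulus assignment depends only on
geometry and the static mask and is computed once per run.

Per frame, each annulus gets a mean μ_r and standard deviation σ_r after
three rounds of one-sided 3σ clipping (Bragg peaks bias naive ring
statistics upward; the clip also removes sentinel-valued pixels without
needing them in the map). Candidate pixels are good pixels above
max(adc_threshold, μ_r + min_snr·σ_r); candidates are grouped by
8-connectivity, size-filtered to [min_pix, max_pix], and summarized by the
background-subtracted intensity-weighted centroid, intensity
I = Σ(v − μ_r), and SNR = I/√(Σσ_r²) over member pixels. Defaults
(min_snr 6, adc 10, min_pix 2, max_pix 200) are the conventional values
for this family of algorithms and are configurable.

Fast mode replaces full-ring statistics by at most 100 randomly chosen
pixels per annulus. The sample positions are drawn once per annulus map
from a stored seed — not per frame — which makes the fast path
reproducible and cheap; whenever an annulus has at most 100 good pixels
the fast statistics equal the full ones exactly.

## Indexing

The autoindexer reconstructs direct-space lattice vectors from the mapped
peak positions:

1. Order peaks by descending intensity and keep the strongest
   `max_points` (2000; 120 in fast mode). If the number of point triplets
   exceeds `max_triplets` (20000; 10000 in fast mode), draw that many
   distinct triples at random (seeded); otherwise enumerate all.
2. Each non-collinear triplet defines a plane; because differences of
   reciprocal-lattice points are reciprocal-lattice vectors, the plane
   normal n̂ is parallel to some direct-space lattice vector. Project all
   peaks onto n̂: d_i = **q**_i · n̂.
3. Histogram the d_i into 1024 bins spanning [min d, max d] (bin 0 = most
   negative, last bin closed), Fourier-transform, and take the largest
   magnitude at index k within the direct-length band; the implied direct
   length is L = k/R for projected range R. The DC term is excluded, and
   the band [direct_length_min, 1.2 × longest reference axis] both
   suppresses low-frequency leakage and bounds the search.
4. With p₀ = 1/L, multiplicities m_i = round(d_i/p₀), and fitting points
   |d_i − m_i p₀| ≤ 0.15·p₀ with m_i ≠ 0 (the origin slab carries no
   period information), refine by the closed form p̂ = Σm_i d_i / Σm_i².
   The fit count is then re-evaluated at p̂ and the candidate accepted only
   if **more than six** points still fit.
5. Each accepted candidate is polished by a 3D least-squares fit
   t = argmin Σ(**q**_i·**t** − m_i)² over its fitting points. This is the
   joint direction+length generalization of the 1D repeat fit and is
   essential: a triplet normal inherits degree-scale direction noise from
   the excitation-error displacement of Ewald-mapped peaks, which no
   refinement of the length alone can remove.
6. Candidates equal up to sign (1% length, 3° direction) merge, keeping
   the highest fit count. Before basis assembly, candidates with fewer
   than `candidate_fit_fraction` (default 0.75) of the best candidate's
   fits are dropped: with a 0.15 fit tolerance and N peaks, random
   directions fit ≈ 0.3·N points by chance and sub-lattice vectors
   (e.g. half-vectors) fit ≈ N/2, so the raw more-than-six rule alone
   cannot separate true lattice vectors (which fit ≈ N) from impostors.
7. Three-vector combinations are tried in order of increasing total
   length (budget 100): unit-vector scalar triple product above 0.05,
   volume within 10% of the reference volume when a reference is given,
   basis re-ordered right-handed. The assembled basis is refined once more
   against all points (same linear least squares, three iterations), and
   the result is verified against the reference with `check_cell`.

Failure at any stage is a result object with a reason label, not an
exception. One RNG per indexing call, seeded from the options (in the
pipeline: derived from the global seed and the frame id), makes runs
bit-reproducible at any worker count. Optional retry-after-deleting-the-
weakest-peaks (2 peaks per attempt, up to 5 attempts) exists but is OFF by
default: that is the real-time configuration, where a second attempt costs
more than it returns.

## Cell comparison and counting

`niggli_reduce` implements the Krivý–Gruber conditional steps applied
directly to the basis vectors through det = +1 integer transforms
(relative tolerance 10⁻⁵), so the reduced cell is connected to the input
by a unimodular change of basis and right-handedness is preserved; sign
normalization of the metric cross terms uses only proper pair flips, which
suffices because the sign of ξηζ is a lattice invariant. The reduction is
idempotent and, over random unimodular re-expressions, agrees with gemmi's
implementation (test oracle).

`check_cell` compares candidate and reference after reduction: matched
when every axis agrees within 5% (relative, symmetric) and every angle
within 1.5° — parameter-wise tolerances are simpler to calibrate than a
G6 metric radius, and the G6 vectors are still reported for diagnostics.

`count_unique_reflections` enumerates Miller indices, applies the Laue
group (−1 or 4/mmm, tetragonal axis = c), merges Friedel mates, and takes
the lexicographically greatest equivalent as class representative.
Conventions frozen after checking them against the deposited tetragonal
cell: both resolution bounds inclusive with 10⁻⁹ relative slack (the class
(44 0 0) of the 79.2 Å cell lies at exactly d = 1.80 Å and must not be
lost to floating-point rounding); systematically absent classes included,
because indexing and merging cannot know the space group; `d_max = None`
means no low-resolution cutoff — the headline count for the reference cell
is the *complete* class count to 1.80 Å, and a printed low-resolution
figure is the rounded resolution of the lowest measured reflection, not a
hard cutoff.

## Prediction, integration, hits

A still excites a reflection when its reciprocal point is close enough to
the Ewald sphere. The band |e| ≤ e_abs + e_rel·|q| (defaults 0.001 Å⁻¹ and
0.002·|q|) is the minimal linear-in-resolution convention for stills;
both terms are configurable and the simulator uses the same form, so
simulation and prediction are exact duals (the simulated hkl set equals
the on-detector predicted set at the same tolerance). Integration sums a
disc of radius 4 px minus the median of a [5, 7] px annulus (median
rather than mean: robust to neighbouring spots), with
σ = √(disc counts + n·annulus variance); a disc touching a bad pixel is
flagged rather than measured. A frame is a "hit" when at least
`min_peaks` (default 15) peaks were found; blanks leave the pipeline
right after the peak search.

## The simulator and what it does (not) show

`simulate_peaks` rotates a known cell to a Haar-uniform orientation
(quaternion construction), selects reciprocal points inside the excitation
band, projects them to the detector, and optionally jitters positions,
drops a fraction, and appends spurious uniform peaks with exponential
intensities. `render_frame` draws Poisson background plus deterministic
Gaussian spots (integrating to the peak intensity up to 4σ tail
truncation) and stamps sentinel pixels; `make_run` interleaves hits and
blanks at a chosen hit fraction with a truth manifest. All randomness
comes from named seeds.

Default study conditions (chosen once): a 512×512 px, 0.1 mm-pixel panel
at 60 mm and λ = 1.0332 Å (12 keV) with excitation half-width 2×10⁻⁴ Å⁻¹
and d_min = 3 Å, which yields ≈26–60 reflections per still for the
79.2 × 79.2 × 38 Å tetragonal test cell — a realistic well-exposed
lysozyme-like still at desk scale. The *narrow* band is what makes these
patterns genuinely noise-free: mapped peak positions sit within 2×10⁻⁴ Å⁻¹
of exact lattice points. Widening the band to the integration default
emulates partiality-width displacement instead, and measurably degrades
recovered cell accuracy — that regime is exercised separately.

What passing synthetic tests does **not** show: real detector
point-spread, gain and saturation behaviour; structure-factor/polarization
intensity statistics; multi-crystal frames; inaccurate geometry
calibration. Results on real data depend on those.

## Profiling and pipeline

Each processing-loop iteration produces one wall-clock timing tree
(root = the whole iteration) whether or not the frame completed the full
arc; unattributed parent time stays with the parent's name, so flattened
categories sum exactly to the root duration. Aggregation averages records
in completion order in consecutive batches (final partial batch kept),
ranks categories by whole-input total (per-batch ranking is unstable),
keeps the ten largest and folds the rest into "other"; conservation is
exact by construction. Absolute timings are hardware-dependent and are
deliberately not asserted anywhere.

`run_pipeline` consumes either an in-memory `RunStream` (consumer-group
delivery, 3 s default polling timeout, messages evicted once every group
has passed them) or a plain frame list. Per-frame seeds derived from
(global seed, frame id) and a final sort by frame id make the stream
output bit-identical for any worker count. Each run writes one stream;
one record per frame.

## Problem sizes used by the checks

The statistical suites run at sizes chosen to make their rates
well-determined while staying desk-scale: 200 patterns for the
parameter-recovery and fast/full concordance protocols (success ≥ 90%,
concordance within 5 percentage points), 50 rendered frames for peak-search
concordance (≥ 95% mutual matching within 2 px), 100 no-lattice patterns
for the false-positive bound, 1000 random unimodular transforms for
reduction invariance, and a 200-frame run for worker-count determinism.
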