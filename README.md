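# serialindex

A self-contained toolkit for processing **serial crystallography still
images**: each frame is a single diffraction snapshot from one small
crystal, and the pipeline must find the Bragg peaks, determine the crystal
orientation and unit cell from nothing but those peak positions
(*indexing*), verify the cell against the known reference lattice, and
measure the reflection intensities — fast enough that a beamline can do it
in real time, frame by frame, without parking data on disk first.

The package is aimed at beamline software developers and method developers
who need the full processing chain — peak search, autoindexing, cell
comparison, prediction/integration, profiling and stream plumbing — in
testable, hermetic form: a built-in simulator generates stills with known
ground-truth cells and orientations, so every stage can be validated
without real detector data.

## What is inside

- **`geometry`** — single-panel detector model; pixel ↔ laboratory-frame
  mapping (beam along +z, detector at z = camera length); Ewald-sphere
  mapping of peaks to scattering vectors **q** = (ŝ − ẑ)/λ; bad-pixel masks
  from pixel rectangles, laboratory rectangles (converted once per geometry
  to pixel ranges) and the 65535 sentinel value; n×n pixel binning.
- **`peaks`** — peakfinder8-style Bragg search: per-pixel assignment to
  thin annuli around the beam centre is precomputed once per run; per-frame
  background mean μ_r and σ_r per annulus (3-round 3σ clip); pixels above
  max(ADC floor, μ_r + SNR·σ_r) are 8-connected into spots. A fast mode
  estimates ring statistics from ≤100 fixed random pixels per annulus.
- **`lattice`** — `UnitCell` with cached reciprocal matrix, so a
  scattering vector **q**(hkl) = h**a\*** + k**b\*** + l**c\*** is one
  matrix product with no trigonometry on the per-reflection path;
  Krivý–Gruber Niggli reduction; reference-cell comparison on the reduced
  cells (with G6 vectors reported for diagnostics); counting of
  symmetry-unique reflection classes under Laue groups −1 and 4/mmm.
- **`asdf`** — the FFT autoindexer. Reciprocal-space peak triplets define
  plane normals; all peaks are projected onto each normal, the projected
  distances are histogrammed into 1024 bins and Fourier-transformed, and
  the strongest in-band frequency gives a candidate direct-space lattice
  vector **t** with |**t**| = k/R. Candidates are refined by least squares,
  accepted when more than six peaks lie close to integer multiples of the
  repeat, merged, and assembled into the three shortest independent basis
  vectors subject to a unit-cell volume constraint from the reference cell.
- **`predict` / `integrate`** — reflections within an excitation-error
  band |e| ≤ e_abs + e_rel·|q| of the Ewald sphere are projected onto the
  detector and measured as disc sums over a median-annulus local
  background.
- **`simulate`** — the exact dual of prediction: ground-truth cells at
  uniformly random orientations, peak lists with optional jitter /
  dropouts / spurious peaks, rendered Poisson-background frames, and whole
  runs with a controlled hit fraction plus a truth manifest.
- **`profile`** — per-frame hierarchical wall-clock timing trees and the
  batched "ten largest categories + other" aggregation used for
  stacked-area throughput reports.
- **`pipeline_io`** — an in-memory run stream with consumer-group
  semantics (each message to exactly one consumer per group; every group
  sees every message), HDF5 batch files of 1000 frames linked by a virtual
  master, a chunked text stream format that round-trips at full precision,
  and `run_pipeline` gluing the whole chain together with results that are
  independent of the worker count.

## Worked example

```python
from serialindex import (
    AsdfOptions, asdf_index, cell_from_parameters, check_cell,
    count_unique_reflections, default_geometry, simulate_peaks,
)

geometry = default_geometry()
reference = cell_from_parameters(79.2, 79.2, 38.0, 90, 90, 90)

pattern = simulate_peaks(seed=3)
print(f"simulated still with {len(pattern.peaks)} peaks")

result = asdf_index(pattern.peaks, geometry, reference, AsdfOptions(rng_seed=1))
print(f"indexing success: {result.success}")
a, b, c, al, be, ga = result.cell.parameters
print(f"recovered cell: a={a:.3f} b={b:.3f} c={c:.3f} A, "
      f"alpha={al:.3f} beta={be:.3f} gamma={ga:.3f} deg")

match = check_cell(result.cell, pattern.true_cell, tol_length=0.01, tol_angle=0.5)
print(f"matches ground truth: {match.matched} "
      f"(length dev {match.length_reldev:.2e}, angle dev {match.angle_dev:.3f} deg)")

n_unique = count_unique_reflections(reference, "4/mmm", None, 1.80)
print(f"unique reflections to 1.80 A under Laue 4/mmm: {n_unique}")
```

prints

```
simulated still with 42 peaks
indexing success: True
recovered cell: a=37.999 b=79.169 c=79.188 A, alpha=90.027 beta=89.987 gamma=89.979 deg
matches ground truth: True (length dev 3.97e-04, angle dev 0.027 deg)
unique reflections to 1.80 A under Laue 4/mmm: 11716
```

The recovered cell is reported in its Niggli-reduced-compatible lab-frame
setting (shortest axis first), so a = 38 Å appears before the two 79.2 Å
axes; `check_cell` compares reduced cells, making the comparison
representation-independent.

The same chain is available from a shell:

```bash
serialindex simulate --n-frames 100 --hit-fraction 0.5 --seed 4 --out-dir run0
python -c "from serialindex.lattice import *; \
    write_cell('cell.txt', cell_from_parameters(79.2, 79.2, 38, 90, 90, 90))"
serialindex run --geometry run0/geometry.geom --cell cell.txt \
    --input run0/master.h5 --output run0.stream --seed 7 -j 4 --profile-out prof.json
serialindex profile-report --records prof.json --batch-size 50 --out prof.tsv
```

## Scope

Single-panel detectors only; no multi-panel geometry refinement, adaptive
gain calibration, alternative indexing engines, partiality modelling or
merging statistics — those belong to the surrounding ecosystem, not this
package. See `docs/methods.md` for the model details, parameter defaults
and known limitations.
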