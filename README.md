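# mwchamber

Desk-scale simulator and classifier for a multi-port microwave sensing
chamber around a 2D tissue phantom. The pipeline is:

1. **phantom** — layered 2D shoulder-analog (skin / muscle / tendon / bone /
   synovial-fluid inclusion) immersed in a lossy matching medium, with
   dehydration scaling of the tissue permittivities and rigid in-plane
   position perturbations.
2. **em_forward** — scalar 2D time-harmonic FEM (P1 triangles) of the
   chamber at 1 GHz: Dirichlet metallic walls, single-mode waveguide-port
   boundary conditions with half-sine aperture profiles, one sparse LU
   factorization reused for all transmitting ports, and mode-overlap
   S-matrix extraction.
3. **analytic_oracle** — partial-wave (Bessel/Hankel) series for dielectric
   cylinder scattering plus S-matrix power-balance checks, used to validate
   the FEM solver independently.
4. **scenarios** — differential S-parameters (loaded minus empty chamber),
   multiplicative Gaussian noise in dB, and labeled datasets for the four
   experiment designs (noise levels, dehydration, phantom position,
   shuffled large dataset). Forward solves are cached per distinct phantom.
5. **classify** — linear soft-margin SVM with C grid search
   (cross-validated), confusion-matrix metrics (healthy = positive class)
   and PCA projections for visualization.
6. **runner** — CLI, YAML manifests, HDF5/Touchstone/JSON persistence and a
   solver validation suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact table
arithmetic, dataset counts, solver validation properties, and the
scaled-down classification runs); the rest are unit/property tests per
module.

## CLI

```sh
mwchamber validate               # solver validation suite (pass/fail table)
mwchamber simulate --n-ports 16 --out smatrix   # Touchstone .s16p
mwchamber reproduce noise --seed 1 --out runs/  # scaled-down noise study
mwchamber evaluate manifest.yaml --out runs/    # YAML-driven experiment
```

Exit codes: 0 success, 2 validation failure, 3 configuration error.

## Known limitation

The shuffled 31-position experiment plateaus near 97% test accuracy with the
linear kernel (the corresponding acceptance test is deliberately left
failing). Errors concentrate at the 10 dB noise level across all positions;
an RBF kernel on the same features reaches ~99.6%, and every single-position
or 0.5 cm leave-position-out design reaches 100%, so the limitation is the
capacity of one linear boundary across 31 placements in the 2D reduction,
not the forward model or the dataset pipeline.

## Geometry defaults

Chamber: circle of diameter 24 cm, 32 (configurable) ceramic-loaded
waveguide apertures of width 2.1 cm (loaded cutoff 0.93 GHz). Body:
14×11 cm ellipse with a 2 mm skin ring; bone disk (r = 1.6 cm) at
(3.5, 0) cm with a 1 cm tendon band; the injury is a 2.0×1.0 cm ellipse at
(5.5, 0) cm filled with synovial fluid (cross-section scale of a 1.4 mL
ellipsoid), or with muscle in the healthy phantom. The matching medium is
fixed at the muscle permittivity 54.8−17.43i. All geometry is configurable
via `GeometryConfig`.
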