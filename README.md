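# mewpdq

Joint regional quantification of Thorium-227 and Radium-223 from
multi-energy-window, low-count SPECT projections — without image
reconstruction.

A patient treated with Th-227 also carries its decay product Ra-223, and
every energy window of a SPECT acquisition records counts from both
isotopes (crosstalk). `mewpdq` estimates the mean activity concentration
of *both* isotopes in a small set of volumes of interest (VOIs) directly
from the projection data by joint Poisson maximum likelihood over
multiple energy windows, where the spectral differences between the
isotopes make the two-isotope problem well conditioned. The package
contains everything needed to evaluate the method end to end with no
external data:

* line spectra, detector energy response, and energy-window modeling;
* digital pelvic phantoms (background / bone / gut / lesion), lumpy
  intra-regional heterogeneity, sampled virtual-trial populations, and
  rigid misregistration perturbations;
* a simplified SPECT projector (rotation, attenuation, depth-dependent
  collimator blur, scatter surrogate, stray background) with
  machine-precision exact adjoints;
* the projection-domain EM estimator (MEW-PDQ);
* Fisher-information / CRLB machinery for estimator efficiency and
  energy-window design studies;
* reconstruct-then-quantify baselines: dual-isotope OSEM (DOSEM) with
  VOI means, and geometric-transfer-matrix (GTM) partial-volume
  correction;
* desk-scale experiment runners (convergence, sweeps, virtual imaging
  trial, heterogeneity and misregistration robustness) plus a thin CLI.

See `docs/methods.md` for the full model, defaults, and caveats.

## Quick start

```python
from mewpdq.estimator import run_mew_pdq
from mewpdq.experiments import calibrate_geometry, desk_config, standard_setup
from mewpdq.system import simulate_projections

config = desk_config()                      # 1-CPU study profile
geometry = calibrate_geometry(config)       # hit the low-count regime
phantom, uptake, sysmat = standard_setup(config, geometry)

data = simulate_projections(sysmat, uptake, seed=7)
estimate = run_mew_pdq(data, sysmat, max_iter=1000)
print(estimate.lambda_th, estimate.lambda_ra)   # Bq/mL per VOI
```

Running `python examples/quantify_single_patient.py` produces (seed 7):

```
simulated 225514 detected counts
EM ran 1000 iterations; final log-likelihood 40990.1

region      isotope          truth  estimate  error %  CRLB %
background  Th227           1230.3    1246.1      1.3     0.8
bone        Th227           3075.8    3060.6     -0.5     1.2
gut         Th227          10252.5   10262.7      0.1     1.2
lesion      Th227          30757.6   31617.2      2.8     3.5
background  Ra223chain       234.2     225.6     -3.6     2.9
bone        Ra223chain       585.4     598.0      2.2     3.8
gut         Ra223chain      2927.0    2956.4      1.0     2.7
lesion      Ra223chain      2341.6    1797.1    -23.3    25.5
```

Note the last column: per-region errors track the CRLB-derived precision
floor. The Ra-223 lesion is the intrinsically hard cell at this count
level (≈ 2e5 detected counts) — its single-realization error is noise,
not bias, as the ensemble studies show.

`python examples/window_design_study.py` shows why four windows are
used: restricting to the shared X-ray window alone leaves the two
isotopes nearly unidentifiable (CRLB-NSD of hundreds of percent), while
all four windows cut the bound by ≥ 99% in every cell.

## Command line

```sh
mewpdq make-phantom --lesion-diameter 33.75 --out phantom/
mewpdq build-sysmat --phantom phantom/ --n-angles 24 --out sysmat.h5
mewpdq simulate --phantom phantom/ --sysmat sysmat.h5 --seed 7 --out counts.txt
mewpdq estimate --projections counts.txt --sysmat sysmat.h5 --out estimate.json
mewpdq experiment vit --seed 0 --out-dir results/vit
```

See `examples/cli_walkthrough.sh` for the complete runnable sequence.

## Evaluation studies

`scripts/acceptance.py` runs the four headline desk-scale studies
(virtual-trial ensemble bias, EM convergence protocol, window
information gain, baseline-dominance ratio) and writes their figures to
JSON:

```sh
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The whole run targets ~15 minutes on one CPU. Statistical caveats for
the trial-level figures (notably the Ra-lesion ensemble bias, whose
measurement standard error is several percent at 96 patients) are
discussed in `docs/methods.md` §8.

## Tests

```sh
python -m pytest
```

The suite covers analytic oracles (quadrature of the energy response,
point-source count conservation, brute-force Fisher information,
closed-form EM solutions), model invariants (exact adjoints, likelihood
monotonicity, mean-preserving textures, bitwise seed determinism), error
handling, and the desk-scale study-level checks.
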