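# sgckit

Directed spectral synchrony analysis for very short multi-trial LFP epochs:
multi-trial autoregressive (VAR) spectral estimation of power, coherence and
spectral Granger causality (sGC), bootstrap/permutation inference on directed
spectra, and SVM decoding of a two-level behavioral condition from top-down
beta-peak sGC patterns with delete-d jackknife validation. A synthetic
VAR-oscillator generator makes the whole chain testable without any external
data.

## What's inside

| module | contents |
| --- | --- |
| `sgckit.synth` | ground-truth oscillator networks (`NetworkSpec`, `ConditionPairSpec`), exact VAR realization (`build_var`), trial simulation with 1/f background and optional instantaneous mixing (`simulate_trials`) |
| `sgckit.spectral` | ensemble-mean subtraction, pooled multi-trial VAR fitting (`fit_var`), AIC order scan, transfer-function spectra with Geweke directed sGC (`model_spectra`, `pairwise_spectra`), time-domain GC, robust 1/f background removal (`remove_background`) |
| `sgckit.inference` | paired bootstrap spectra, omnibus-corrected directional asymmetry, spectral peak finding with a trial-shuffle null threshold, consistent-pair selection, time-reversal spuriousness control, coherence-vs-sGC correlation |
| `sgckit.decoding` | split-half SVM decoding of the condition from nearest-to-16 Hz directed peak magnitudes, JSVE / delete-d jackknife standard errors, random-frequency control |
| `sgckit.io`, `sgckit.config`, `sgckit.pipeline`, `sgckit.cli` | HDF5 / CSV ensemble containers, YAML run configuration (defaults anchored to the reference protocol), end-to-end pipeline driver, CLI |

## Quick start (Python)

```python
import numpy as np
from sgckit import (ConditionPairSpec, simulate_trials, bootstrap_spectra,
                    directional_asymmetry, decode_context)
from sgckit.spectral import subtract_ensemble_mean
from sgckit.synth import canonical_network

spec = ConditionPairSpec(
    base=canonical_network(),
    condition_deltas={"contingency1": {("H1", "L1"): 1.3},
                      "contingency2": {("H1", "L1"): 0.7}},
    trials_per_condition=2000, samples_per_trial=17, seed=7,
)
ens = subtract_ensemble_mean(simulate_trials(spec))
pairs = [("H1", "L1"), ("H2", "L2")]

boots = bootstrap_spectra(ens, pairs, order=10, B=1000, seed=1)
asym = directional_asymmetry(
    np.mean([boots.sgc[(h, l)] for h, l in pairs], axis=0),
    np.mean([boots.sgc[(l, h)] for h, l in pairs], axis=0),
    n=ens.n_trials, alpha=0.001, freqs=boots.freqs,
)
print("significant band:", asym.significant_freqs())

result = decode_context(ens, pairs, B_exemplars=200, repeats=200, seed=2)
print(result.mean_accuracy, result.p_value)
```

## CLI

```bash
sgckit simulate --config config.yaml --out ensemble.h5
sgckit spectra  --input ensemble.h5 --out spectra.csv --n-boot 1000 --seed 1
sgckit asymmetry --input ensemble.h5 --out asymmetry.csv
sgckit peaks    --input ensemble.h5 --out peaks.csv
sgckit trtest   --input ensemble.h5 --out trtest.csv --band-lo 8 --band-hi 23
sgckit decode   --input ensemble.h5 --out decoding.json --repeats 5000
sgckit report   --config config.yaml       # full pipeline
```

A config file is plain YAML; `RunConfig()` defaults carry the reference
protocol values (order 10 chosen by AIC, 5–90 Hz band, 1000 bootstraps, 1000
null permutations, two-tailed p < 0.001 asymmetry test, SVM cost 1 with 200
exemplars and 5000 repeats).

## Notes and caveats

- sGC is computed pairwise from bivariate models (no conditional/multivariate
  GC), matching the reference protocol; the instantaneous term is the
  remainder of the total interdependence and may dip below zero at single
  frequencies when innovations are correlated.
- Feature z-scoring in the decoder pools train and test exemplars (the
  protocol's "balanced" convention). This leaks normalization statistics
  across the split; `decode_context(..., leakage_free=True)` computes them
  from the training blocks only.
- The time-reversal t-test defaults to frequency bins as replicates
  (protocol-faithful) but AR spectra are smooth, making that unit
  anticonservative under the null; `unit="trial_splits"` gives a calibrated
  test and is used by the acceptance checks.
- Generator amplitudes are arbitrary units; all directed measures are
  scale-free.
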