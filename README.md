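# alstim

Active-learning experimental design for brain-stimulation parameter
sweeps.

Tuning a brain-stimulation therapy means learning how the brain responds
to the stimulation parameters — amplitude, frequency, and pulse width —
where the response is a spectral-power biomarker (beta power for
Parkinsonian circuits, theta or slow-gamma power for hippocampal ones).
Every sample costs experiment time on a live subject, so the order in
which parameter sets are administered matters. `alstim` implements
pool-based **active learning (AL)** for this regression problem: the
model in training picks the next stimulation parameters itself, and an
in-silico benchmarking harness quantifies how much fewer samples AL needs
than uniform **random sampling (RS)**.

The package is aimed at researchers designing closed-loop stimulation
experiments (electrical DBS or optogenetic) who want to pre-select a
query strategy and regression model in simulation before spending animal
or patient time.

## What is inside

- **Query strategies** (module `alstim.query`): query-by-committee
  (QBC, maximize bootstrap-committee prediction variance
  σₙ = (1/P) Σₚ (yₙᵖ − ȳₙ)²), expected model change maximization
  (EMCM, maximize (1/P) Σₚ ‖(yₙᵖ − ŷₙ) uₙ‖), greedy sampling (GS,
  maximize minₘ ‖uₙ − uₘ‖ over labeled m), representativeness & diversity
  (RD, k-means with k = labeled+1, query the largest labeled-free
  cluster), the RD-integrated variants rd_qbc / rd_emcm / rd_gs, and the
  enhanced EQBC / EEMCM with outlier-safe clustered initialization —
  nine AL strategies plus the RS baseline.
- **Regressors** (`alstim.regressors`): ridge, linear- and RBF-kernel
  SVR, and Gaussian process regression behind one deterministic
  fit/predict contract, plus the bootstrap committee builder.
- **Episode & benchmark harness** (`alstim.harness`): the three-phase
  loop (initial sampling → model improvement → validation), the
  AUC_RMSE curve summary, brain-state and stochastic-response dynamic
  modes, and the repeated paired AL-vs-RS benchmark.
- **Statistics** (`alstim.stats_report`): paired t-tests with Bonferroni
  correction (0.05/9 ≈ 0.0056) and the ΔAUC_RMSE comparison matrix.
- **Synthetic datasets** (`alstim.synthetic`): seeded surrogate
  generators for a 200-sample DBS beta-power sweep, a 100-combination
  grid with 4 repeated sessions, a 72-combination optogenetic sweep, and
  band-limited LFP-like signals.
- **Spectral features** (`alstim.signal_features`): Thomson multitaper
  band power (5 s windows, 0.1 s step, TW = 3, K = 5 tapers) with
  zero-phase low-pass and mains-notch preprocessing.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Benchmark ridge regression with two query strategies against random
sampling on the synthetic Parkinsonian sweep (200 parameter sets, 40
held out per repeat, models grown from 3 to 20 training samples):

```python
from alstim import run_benchmark, summary_matrix, bonferroni_threshold, EpisodeConfig
from alstim.query import StrategyConfig
from alstim.regressors import RegressorSpec

ridge = RegressorSpec(family="ridge")
configs = [EpisodeConfig(strategy=StrategyConfig(name=n), regressor=ridge)
           for n in ("rs", "qbc", "gs")]
result = run_benchmark("pd_sweep", configs, repeats=200, base_seed=1)
for name in result.strategies:
    print(f"mean AUC_RMSE[{name}] = {result.column(name).mean():.3f}")
matrix = summary_matrix([result], corrected_alpha=bonferroni_threshold(0.05, 9))
print(matrix.to_frame().to_string(index=False))
```

prints

```
mean AUC_RMSE[rs] = 4.732
mean AUC_RMSE[qbc] = 4.578
mean AUC_RMSE[gs] = 4.428
strategy condition  mean_diff       pvalue  significant  n_repeats
     qbc  pd_sweep  -0.153734 2.293503e-03         True        200
      gs  pd_sweep  -0.303795 3.134351e-09         True        200
```

Both AL strategies reach a lower area under the RMSE-vs-samples curve
than random sampling — the same model quality with fewer administered
stimulations — and the paired t-test on the 200 shared-split repeats puts
both below the Bonferroni-corrected threshold of 0.0056.

The same benchmark from the shell:

```sh
alstim generate --preset pd_sweep --seed 1 --out pd.csv
alstim benchmark --preset pd_sweep --strategies rs,qbc,gs --repeats 200 --seed 1 --out bench/
alstim report bench/ --out comparison
```

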