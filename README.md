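# phispike

Integrated-information (Φ) estimation for binarized spike-train data.

The package computes the autoregressive integrated-information coefficient
of a neural population from second-order statistics of its binary on/off
state sequence, under three partition strategies:

- **MIB** — exhaustive minimum-information-bipartition search (practical up
  to ~15 neurons; `2^(N-1) - 1` candidates),
- **atomic** — every neuron its own subset (fastest, ignores cluster
  structure),
- **Louvain** — a community partition from a from-scratch two-phase Louvain
  modularity optimizer run on a significance-thresholded spike-correlation
  matrix.

Supporting machinery: spike-table loading and 30 ms binarization,
Bernoulli-variance neuron ranking with an iterative removal loop for
rank-deficient covariances, top-k neuron selection, lag (Δt) optimization
by Φ maximization, per-period session analysis with reward-rate
normalization, Spearman/Bonferroni correlation of Φ against behavioral
success, and seeded synthetic generators (independent, coupled
linear-threshold networks with planted communities and delays, and
reward-linked multi-period sessions) so the whole pipeline is testable
without any external data.

## Library quick start

```python
import phispike as ps

spec = ps.GeneratorSpec(n_neurons=16, duration_s=300, bin_size=0.03,
                        base_rate=0.15, coupling=0.5, communities=(8, 8),
                        seed=42)
session = ps.gen_coupled(spec)
binned = ps.binarize(session, bin_size=0.03)

result = ps.robust_phi(binned, method="louvain", lag_bins=1)
print(result.phi, result.partition.subsets, result.warnings)
```

The discrete-entropy estimator `ps.phi_discrete` (systems of up to 10
binary nodes) provides an independent cross-check of the autoregressive
value in the small-system limit.

## CLI

The console script `phi-spike` wires the modules into pipelines:

```sh
phi-spike simulate --seed 1 --n-neurons 20 --coupling 0.4 --out sim/
phi-spike binarize sim/spikes.csv --bin-size 0.03 --out binned.csv
phi-spike phi sim/spikes.csv --method mib --top-k 15 --out phi.json
phi-spike sweep-dt sim/spikes.csv --method atomic --max-lag 40 --out sweep.csv
phi-spike correlate sim/spikes.csv --events sim/events.csv --method atomic
phi-spike run sim/spikes.csv --events sim/events.csv --method louvain15 \
    --lag-bins auto --out run/
```

`run` writes a per-period table (`periods.csv`), an optional lag-sweep
table, a correlation report JSON with Bonferroni-corrected significance,
and a run log capturing the seed and removal history. Methods suffixed
`15` (`mib15`, `atomic15`, `louvain15`) first restrict to the 15 neurons
with the highest Bernoulli variance.

Input formats: spike CSV with header `neuron_id,time_s` (one spike per
row) or a directory of per-neuron whitespace-separated time lists; event
CSV with header `time_s,label`.

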