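# wmnet

Small-world functional network analysis of block-design working-memory
fMRI node time series.

Working-memory studies in schizophrenia compare functional brain networks
between patients (SZ) and healthy controls (HC) as memory load varies.
`wmnet` implements that analysis as a tested, reusable pipeline: from
per-run node time courses of a Sternberg item-recognition task (loads of
1, 3 and 5 digits), through load-wise partial-correlation networks and
degree-uniform small-world thresholding, to the group x load statistics.
Because patient scan data of this kind are not publicly deposited, the
package includes a first-class synthetic-cohort generator that plants a
known ground-truth network deficit, so every stage — and the full pattern
of group differences — can be validated end to end.

## The method

For each subject and load level the pipeline:

1. **Preprocesses** node time series: zero-phase Butterworth band-pass
   with cutoffs `[0.01, 0.9] x Nyquist` (0.0025–0.225 Hz at TR = 2 s),
   then cuts each run into task blocks (discarding the 2 s prompt,
   keeping the 6 s encode + 38 s probe span) and concatenates all blocks
   of the same load.
2. **Builds connectivity**: partial correlations computed jointly against
   all other nodes via the precision matrix,
   `r_ij = -P_ij / sqrt(P_ii P_jj)` with `P` the inverse of a
   Ledoit–Wolf-shrunk sample covariance, followed by the Fisher
   transform `z_ij = arctanh(r_ij)`.
3. **Thresholds** each matrix to a fixed mean degree `K` by keeping the
   `E = round(K N / 2)` strongest edges, so every subject's network has
   the same connection density (`cost = K/(N-1)`).
4. **Measures** the binary graphs: degree/cost, clustering coefficient
   `C_net`, characteristic path length `L_net`, global and local
   efficiency `E_global,net`, `E_local,net`; and the small-worldness
   `sigma = (C_net/C_rand) / (L_net/L_rand)` averaged over 25
   degree-preserving Markov-chain rewired null networks.
5. **Finds the small-world regime**: the degree interval in which every
   network of the cohort is fully connected *and* has mean `sigma > 1`,
   and lays a 16-point fixed-increment observation grid inside it.
6. **Tests**: site-mean correction, two-way group x load ANOVA on the
   grid-averaged measures, per-observation two-sample t-tests with
   Benjamini–Hochberg FDR across the 16 observations, one-tailed paired
   load-contrast tests, Pearson correlations between measures and
   reaction time, and head-motion summaries.

## Worked example

```python
from wmnet.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=8, n_per_group=6, n_nulls=10))
print(result.summary["regime"]["k_min"], result.summary["regime"]["k_max"])
print(result.summary["regime_check"])
print(result.summary["interaction_p"])
print(result.summary["load_with_most_C_net_differences"])
```

prints (seed 8, six subjects per group):

```
4.5 10.2
{'all_connected': True, 'min_sigma': 1.3726848047419538, 'n_networks_x_degrees': 576}
{'C_net': 1.6318408273744883e-06, 'L_net': 8.860992020461675e-08, 'E_local': 1.0606123849021823e-06, 'E_global': 7.243290724060564e-08}
L3
```

Reading: the cohort's small-world regime spans mean degrees 4.5–10.2
(every one of the 36 subject x load networks is connected with
`sigma > 1` at all 16 grid degrees — minimum 1.37); the group x load
interaction is significant for all four averaged measures; and the
medium load (L3) is where the clustering deficit concentrates — the
planted patient phenotype, recovered from the simulated BOLD series
alone. The same stages are scriptable from the shell:

```bash
wmnet simulate --out cohort/ --seed 3 --n-per-group 8
wmnet validate cohort/
wmnet run --out results/ --seed 3
```

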