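# Methods

## Scope and data model

`wmnet` analyses node-level BOLD time series from a block-design
working-memory task. The default configuration mirrors a two-site
Sternberg-paradigm study: 105 network nodes (spatial averages of
task-related regions), TR = 2 s, three 6-minute runs each containing two
blocks per load level (L1/L3/L5 digits), every block being a 2 s prompt,
6 s encode and 38 s probe (14 probes). Upstream image processing —
realignment, normalisation, smoothing, ICA-based node definition — is out
of scope; the pipeline's interface is the node x time matrix per run
(an optional voxel-block averaging helper covers the last reduction
step), plus a JSON design schedule, a behavior table and optional
rigid-body motion traces.

## Preprocessing

Runs are band-pass filtered before block extraction with a zero-phase
(forward–backward) Butterworth filter of order 5. The cutoffs are
*computed* from the factors 0.01 and 0.9 applied to the Nyquist frequency
`1/(2 TR)` — 0.0025–0.225 Hz at TR = 2 s — rather than hard-coded; the
band keeps the encode (1/6 s ≈ 0.167 Hz) and probe (1/38 s ≈ 0.026 Hz)
task rhythms. (Rounded prints of this band sometimes appear as
"0.003–0.23 Hz", and 0.5 Hz is occasionally mislabelled the Nyquist
frequency of TR = 2 s — that value is the sampling rate; the factor rule
against the true Nyquist is what is implemented.) Zero-phase application
avoids shifting task-locked structure; order 5 is a conventional
compromise between roll-off and edge transients.

Each run is then cut into blocks on the TR grid: the prompt frame is
discarded, the 22-frame encode+probe span kept. Blocks of the same load
are concatenated in (run, onset) order — 6 x 22 = 132 frames per load in
the default design — with full per-block provenance retained, so the
concatenation is exactly invertible. Concatenation boundaries are left
untapered; the discontinuities are part of the measured procedure.

## Connectivity

Edge weights are partial correlations computed jointly against all other
nodes through the precision matrix: `r_ij = -P_ij / sqrt(P_ii P_jj)`.
With 105 nodes and 132 frames the sample covariance is near-singular, so
the default estimator applies Ledoit–Wolf analytic shrinkage toward the
scaled identity before inversion (`shrinkage="auto"`); a fixed intensity
in [0, 1] may be supplied instead, and `shrinkage=0` reproduces the naive
estimator when the covariance is invertible (raising otherwise, rather
than silently pseudo-inverting). The estimator used is recorded in each
matrix's provenance. The Fisher transform `arctanh` is applied
elementwise; the diagonal is stored as 0 and excluded from all edge
operations. Negative partial correlations are retained in `z` but can
never become edges under the strict `z > T` binarization (an
absolute-value option exists, off by default).

## Networks, metrics, nulls

Degree-uniform thresholding keeps the `E = round(K N / 2)` largest edges,
so each network achieves mean degree within 2/N of the target; ties are
broken lexicographically on (i, j) for determinism. Measures on the
binary graphs: mean degree and cost `K/(N-1)`; clustering `C_i` (0 for
degree < 2 nodes, a convention required to keep the mean defined);
unweighted BFS path lengths with unreachable pairs set to infinity
(propagating to `L_net`); global efficiency as the mean inverse distance
with `1/inf = 0`; local efficiency as the global efficiency of each
node's neighbour-induced subgraph with the node itself removed (the
standard fault-tolerance reading).

Small-worldness compares each network with 25 degree-preserving rewired
nulls: Markov-chain double-edge swaps (default 10·E accepted swaps,
proposals creating self-loops or multi-edges rejected), with
connectedness enforced by continued swapping. Per null,
`sigma = (C/C_rand)/(L/L_rand)`; the ensemble value is the mean of the 25.
The analytic approximations `C_rand = K/N` and `L_rand = ln N / ln K` are
reported as diagnostics only: at N = 105 the clustering approximation is
accurate to ~1% on matched random graphs, but the path-length formula
underestimates the true value by ~20% (it is asymptotic), which is the
quantitative reason the rewired ensemble — not the formulas — defines
sigma.

The small-world regime is searched on a 0.1-degree lattice. `K_min` is
the smallest degree at which every network in the cohort is connected
(exact, by binary search over nested top-E edge sets). `K_max` is the
largest degree at which every network keeps mean sigma above
`1 + sigma_margin` (default margin 0.1–0.15 in the pipeline): the margin
exists because sigma is itself a 25-null Monte-Carlo estimate, and the
regime's promise — strictly `sigma > 1` everywhere on the grid — must
survive re-drawing the null ensemble. Sigma decreases with density in
this regime, which the binary search exploits. The observation grid
takes `grid_size` (16) degrees from `K_min` with the largest 0.1-multiple
increment fitting below `K_max`; applied to a regime of [19.9, 35.0]
this rule reproduces the classical 19.9, 20.9, …, 34.9 grid with
increment 1.0.

Metric monotonicity along the grid (C, E_local, E_global rising and L
falling as edges are added) holds empirically for these cohorts and is
asserted as such; only L non-increasing and E_global non-decreasing are
theorems on nested connected graphs — single counterexamples exist for
clustering under edge addition.

## Statistics

Site effects are removed by subtracting per-site means (grand mean
restored) within each (measure, load, observation) cell — equivalent to
regressing out site, and exactly neutral to group contrasts when groups
are balanced across sites. The two-way group x load ANOVA runs on the
per-subject averages over the 16 observations (one value per subject and
load; subject is not modelled as a repeated-measures factor by default,
matching the simple two-way analysis). Group comparisons at each
observation use pooled-variance two-sample t-tests (Welch optional) with
Benjamini–Hochberg FDR applied within each family of 16 observations.
Load contrasts are one-tailed one-sample t-tests on per-subject
differences, reported per group and direction. Behavior coupling uses
Pearson correlation between the averaged measure and mean correct-trial
reaction time, pooled and per group. Motion summaries are frame-to-frame
displacement statistics (mean/max translation norm, mean rotation norm,
and a movement count above a configurable 0.1 mm threshold — the
threshold is a convention, not an estimate).

## The synthetic cohort generator

The generator exists so the pipeline's full statistical fingerprint can
be validated without scan data. Each subject x load cell carries a
planted connected Watts–Strogatz-style graph (ring lattice plus
rewiring); the rewiring probability is set per (group, load), and higher
rewiring means lower planted clustering. The default table plants the
patient phenotype: 0.05 everywhere except 0.22 for the patient group at
the medium load — producing lower clustering/local efficiency, shorter
paths and higher global efficiency at L3 in patients, a V-shaped patient
load trajectory and a flat control one.

The graph becomes a Gaussian graphical model: precision matrix with
`-c` on edges and diagonal `1 + K_i·c` (strictly diagonally dominant,
hence positive definite), inverted and rescaled to unit diagonal so
block signal and fixation noise share a variance scale (diagonal scaling
leaves partial correlations untouched). This construction is what makes
the *partial*-correlation stage the right inverse of the generator:
non-edges have exactly zero partial correlation.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| nodes | 105 | study configuration |
| planted mean degree | 4 | partial correlations are bounded by ~1/degree under diagonal dominance; at 132 frames/load a sparse strong backbone (edge partial r ≈ 0.24) is recoverable where a degree-20 one (r ≤ 0.05) is statistically invisible |
| coupling `c` | 4.0 | near the saturation of the 1/degree bound |
| rewiring | 0.05 / 0.22 (SZ-L3) | baseline strongly small-world; deficit large enough to detect at scaled n, small enough that patient networks remain small-world (the regime must hold for *every* network) |
| noise_sd | 0.15 | white measurement noise on top of the block covariance |
| drift | 0.15 | slow per-node sinusoids (120–360 s periods); mostly below the task band but not fully removed by the 0.0025 Hz high-pass, as in real data |
| activation | 0.3 | common task-locked boxcar convolved with a canonical double-gamma response; makes the filtering stage consequential |
| RT anchors | 550/636/691 ms (HC), 594/702/764 ms (SZ) | published group means by load; RT = anchor + 350·(cell-mean clustering − subject clustering) + N(0, 55 ms), giving the negative clustering–RT coupling within cells and load-monotone means |
| accuracy anchors | 0.992–0.954, clipped at 0.90 | published group means |
| motion | random-walk steps 0.02 mm (HC) / 0.035 mm (SZ) | group difference in motion exists but is independent of network truth, so motion cannot explain recovered effects |

Fixation gaps fill each run to 6 minutes (84 s split evenly across the
seven gaps in whole TRs). Probe-epoch microstructure (0.6–2.5 s
inter-probe jitter) is not modelled; the probe span is one homogeneous
epoch on the TR grid. Everything is a pure function of (parameters,
seed) via a SeedSequence tree.

What the generator does *not* emulate: voxel-level structure, site-
specific noise spectra, haemodynamic nonlinearity, temporal
autocorrelation of scanner noise, and ICA decomposition variability.
Passing recovery tests therefore demonstrates the pipeline's
correctness and sensitivity under a faithful covariance-structured
model — not performance guarantees on arbitrary real scans.

## Problem sizes used in validation

Cohort-level checks run at scaled sizes chosen for CI practicality while
keeping statistical power: the regime check uses 8 subjects per group
(48 networks x 16 degrees x 25 nulls); the recovery study uses 50
replicate cohorts of 16 per group — the smallest size at which the
pooled reaction-time correlation retains ≥80% power under the default
effect sizes (the interaction and per-observation tests are far above
that). The acceptance script runs the full default 35 per group. The
recovery replicates use a fixed-increment grid anchored just above each
cohort's connectivity bound rather than the full sigma-bounded regime
search, because only the metric statistics — not sigma — enter those
tests.

## Known limitations

- Heavy Ledoit–Wolf shrinkage biases partial correlations toward zero;
  rankings (hence thresholded topology) are what the pipeline relies on.
- With 132 frames and 105 nodes, edge recovery of even the calibrated
  backbone is ~70%; absolute metric values are biased toward random-graph
  values, and only contrasts (group, load) should be interpreted.
- The regime search assumes sigma decreases with density above the
  connectivity bound; cohorts violating that (e.g. extremely sparse
  signal) fail loudly rather than returning a bogus grid.
- The rewiring null enforces connectedness; for graphs whose degree
  sequence admits very few connected realisations this may over-restrict
  the ensemble (a bounded-retry error reports it).
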