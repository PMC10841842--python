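# simpull

Stoichiometry analysis for single-molecule pull-down (SiMPull) photobleaching
data.

In a SiMPull experiment, protein complexes — for example messenger
ribonucleoprotein particles (mRNPs) captured via the nuclear cap-binding
complex — are immobilized on a slide and imaged by TIRF microscopy. Each
fluorescently tagged copy of an RNA-binding protein (RBP) bleaches in a
discrete intensity step, so the per-spot step count reports the number of
*fluorescent* copies in that complex. Two systematic effects separate the
step counts from the true copy numbers:

1. **Incomplete reporter activity.** A tag is fluorescent only with
   probability *p* (≈ 0.74 for mNeonGreen, ≈ 0.78 for labeled SNAPf), so
   counts are thinned binomially.
2. **Zero truncation.** A complex whose tags are all dark is never detected,
   so the count 0 is unobservable and high-copy complexes are
   over-represented among detected spots.

`simpull` models the observed step counts `X` as a finite mixture of
zero-truncated binomials. With `g` sub-populations of copy numbers
`m_1 < … < m_g` and proportions `π_1 … π_g`,

```
P(X = x) = Σ_j π_j · C(m_j, x) p^x (1−p)^(m_j−x) / (1 − (1−p)^(m_j)),   1 ≤ x ≤ m_j
```

Parameters are estimated by maximum likelihood with alternating
maximization — exhaustive grid search over the component sizes at fixed
weights, and EM responsibility updates for the weights at fixed sizes — and
the number of sub-populations is selected by minimizing
`AIC(k) = 2(2k−1) − log L`. The selected fit is converted into the
activity-corrected copy-number distribution by dividing each component
weight by its detection probability `1 − (1−p)^m` and renormalizing.

The package also provides:

- a **synthetic-data generator** reproducing the assumed detection model
  (sub-populations, Bernoulli reporter activity, zero truncation, one-step
  background contaminants, background-only controls, two-color spot fields,
  photobleaching intensity traces);
- **preprocessing**: zero-count removal, step histograms, scaled subtraction
  of non-tagged-control backgrounds, replicate summaries;
- a **bootstrap Kolmogorov–Smirnov test** for comparing discrete step-count
  distributions between conditions (pooled resampling; the continuous-case
  p-value is invalid for counts);
- **two-color co-localization**: affine channel registration from fiducial
  beads, nearest-neighbor spot matching within a pixel radius, control
  subtraction of chance co-localization, single/multicopy classification by
  intensity, reporter-activity correction of occupancy, and rank-correlation
  tests of intensity association;
- a simple **change-point step counter** for the synthetic traces, and an
  end-to-end pipeline with a CLI.

## Worked example

Simulate 5,000 spots from an equal mixture of single-copy and four-copy
complexes at SNAPf activity 0.78, then fit and select:

```sh
$ simpull simulate --components "1:0.5,4:0.5" --activity 0.78 \
    --n 5000 --seed 11 -o counts.tsv
wrote 5000 spots to counts.tsv (625 all-dark draws discarded)

$ simpull select counts.tsv --k-max 4 --m-max 10 --activity 0.78 -o sel.json
selected g=2 sizes=(1, 4) stoichiometry={1: 0.511, 4: 0.489}
```

The 625 discarded draws are the simulated complexes whose reporters were all
dark — about 12.5% of attempts, matching
`0.5·(1−0.78) + 0.5·(1−0.78)⁴ ≈ 0.111` plus sampling noise on the retained
5,000. AIC falls from 10811 at k=1 to 6223 at k=2 and does not improve
further, so two sub-populations are selected, and the corrected
stoichiometry distribution `{1: 0.511, 4: 0.489}` recovers the generative
50/50 truth: the raw counts are biased toward the four-copy class (a
single-copy complex is detected only 78% of the time), and the correction
removes exactly that bias.

The same analysis is available in Python:

```python
from simpull import PopulationSpec, simulate_counts, select_model, \
    FitConfig, corrected_distribution

spec = PopulationSpec(components=((1, 0.5), (4, 0.5)), activity=0.78)
counts = simulate_counts(spec, 5000, seed=11).counts
fits, best = select_model(counts, 0.78, FitConfig(k_max=4, m_max=10))
stoich, implied = corrected_distribution(best)
```

Other entry points: `simpull compare` (bootstrap KS test between two
conditions), `simpull coloc` (two-color co-localization with registration
and activity correction), `simpull steps` (trace step counting),
`simpull report` (full pipeline from a YAML config; see
`examples/demo_config.yaml`).

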