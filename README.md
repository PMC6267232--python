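# mnc — resting-state MEG networks and cognition

`mnc` is a reusable analysis pipeline for studies that relate resting-state
MEG functional network properties to cognitive performance in clinical
cohorts — the setting where ~5 minutes of eyes-closed source-space MEG per
subject (78 cortical atlas regions, 625 Hz, epochs of 4096 samples) is
summarized into band-specific connectivity and network-topology measures
and correlated with neuropsychological z-scores.

The pipeline implements, as tested library code:

- **Phase lag index (PLI)** connectivity: for ROIs *i, j* with
  instantaneous phases φ(t) (angle of the analytic signal of the
  band-limited series),
  `PLI_ij = | ⟨ sign( Δφ_ij(t) ) ⟩_t |`, with Δφ wrapped to (−π, π] and
  exact 0/π differences contributing sign 0 — so strictly zero-lag
  (volume-conduction-like) coupling is discarded.
- **Resting-state-network averaging**: mean PLI over the ROI pairs within
  the default mode network (DMN) and the left/right frontoparietal
  networks (FPN), plus the global mean over all pairs.
- **Minimum spanning tree (MST) topology**: the maximum-total-PLI backbone
  via Kruskal's algorithm, summarized per epoch by maximum degree, leaf
  fraction L/m, mean eccentricity, maximum betweenness centrality BC_max,
  and tree hierarchy `T_H = L / (2 m BC_max)` (m = N−1 edges), averaged
  over epochs per subject.
- **Cognitive z-scores**: raw test scores standardized against matched
  healthy-control norms, oriented so higher = better, averaged into six
  domain composites (executive, psychomotor speed, working memory,
  information processing, attention, verbal memory), with impairment
  flagged at z ≤ −1.5.
- **Nonparametric statistics** written from first principles:
  Mann–Whitney U (exact small-sample p by enumeration, tie-corrected
  normal approximation otherwise) for patient-vs-control comparisons, and
  Kendall tau-b (tie-corrected variance; exact permutation option for
  n ≤ 8) for brain–behaviour associations.
- **A synthetic cohort generator** — coupled phase oscillators with
  controllable within-RSN coupling, per-ROI intrinsic lags and a
  Gaussian-copula link between each subject's DMN coupling strength and
  their working-memory score — so the entire pipeline is testable without
  any patient recordings.

Frequency bands default to theta (4–8 Hz), lower alpha (8–10 Hz) and upper
alpha (10–13 Hz).

## Worked example

Generate a 20-patient / 20-control cohort at the default recording
conditions (78 ROIs, five 4096-sample epochs at 625 Hz, theta band,
coupling–cognition effect 0.5, −0.55 SD working-memory deficit) and run
the headline analysis:

```python
from mnc.pipeline import dmn_working_memory_association
from mnc.spectral import DEFAULT_BANDS
from mnc.synthetic import CohortConfig, generate_cohort

cfg = CohortConfig(seed=0, bands=(DEFAULT_BANDS[0],))   # theta only
cohort = generate_cohort(cfg)
res = dmn_working_memory_association(cohort)
print(res)
```

prints (exactly reproducible for this seed):

```
{'tau': 0.4842, 'tau_p': 0.0028, 'n_patients': 20, 'wm_u': 132.0, 'wm_p': 0.0338}
```

`tau` is the Kendall tau-b between the patients' epoch-averaged within-DMN
theta PLI and their working-memory z-score — positive, as injected
(effect 0.5 attenuates to ≈0.45 after PLI estimation noise) — and `wm_p`
is the one-tailed exact Mann–Whitney p for the patients' working-memory
deficit relative to controls (detected here; at −0.55 SD and n = 20/20 the
test's power is ≈0.50, so roughly half of the seeds detect it).

The full pipeline, producing the three result tables
(`cognition_group.tsv`, `rsn_mst_correlations.tsv`,
`global_correlations.tsv`) plus a JSON manifest:

```sh
mnc run --seed 1 --out results/run1        # full default configuration
mnc synth --out cohort_dir --seed 2        # just write a synthetic cohort
mnc report results/run1                    # pretty-print the tables
```

By default brain–behaviour correlations are computed only for domains
whose patient-vs-control comparison is significant (p < 0.05);
`--all-domains` overrides the gate.

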