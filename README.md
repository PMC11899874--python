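# precimap

Individualized resting-state functional network mapping, at desk scale.

Resting-state fMRI shows that the precise topology of large-scale brain
networks — default mode, dorsal attention, sensorimotor, and so on — is
specific to each individual. Mapping it per subject ("precision functional
mapping") normally requires large amounts of low-motion data, which is hard
to obtain in populations such as infants. `precimap` implements the two main
families of individualized mapping used in that setting, together with the
reliability machinery needed to decide how much data a precise map requires:

* **Template matching.** Per-network templates are built from a cohort:
  each network's mean ("seed") time series is correlated with every
  grayordinate, the seed maps are averaged across subjects, and each map is
  thresholded at mean + 1 SD so only the most connected grayordinates remain.
  A new subject's grayordinate *g* is then assigned to the network *k*
  maximizing the eta-squared similarity between *g*'s whole-brain
  connectivity row and template *k*:

  η²(a, b) = 1 − Σᵢ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σᵢ[(aᵢ−M̄)² + (bᵢ−M̄)²],
  with mᵢ = (aᵢ+bᵢ)/2 and M̄ the grand mean — 1 for identical profiles,
  0 for maximally discordant ones.

* **Community-detection consensus.** The data-driven comparison arm:
  geodesic distance exclusion (pairs within 20 mm dropped), thresholding at
  tie densities 0.3–3.0 %, flow-based (map-equation) community detection per
  density, a 400-grayordinate network-size filter, stringent-to-lenient
  consensus stacking, a 30-grayordinate minimum-region cleanup, and Jaccard
  (≥ 0.2) relabeling onto named reference networks.

* **Reliability analysis.** Split-half normalized mutual information
  NMI = 2·I(A;B)/(H(A)+H(B)) against an inter-subject null, data-amount
  sampling curves (continuous vs. random frame sampling), and an OLS
  regression of within-subject NMI on minutes of retained data.

* **Synthetic cohorts.** Extended-acquisition infant-like datasets are not
  publicly available, so a first-class generator simulates them: a toy
  cortical mesh, a planted group parcellation with per-subject boundary
  perturbations, low-frequency BOLD-like signals with network-structured
  covariance (including sensorimotor anticorrelations), and framewise-
  displacement traces for motion censoring at the 0.3 mm threshold.

The package is aimed at methods researchers who want a tested, transparent
reference implementation of this pipeline that runs in minutes on a laptop,
with every filtering rule (FD 0.3 mm, 2.25 mm smoothing, 1 SD template
threshold, tie densities, size filters, Jaccard 0.2) exposed as a parameter.

## Worked example

```python
import numpy as np
import precimap as pm

# simulate a small cohort of synthetic "infant" subjects
cfg = pm.SimulationConfig(
    n_subjects=4, n_grayordinates=400, n_networks=6,
    duration_minutes=8.0, boundary_jitter=0.2,
    within_network_signal_fraction=0.8, rng_seed=0,
)
cohort = pm.simulate_cohort(cfg)

# smooth, censor, and build the network template set from the cohort
weights = pm.gaussian_smoothing_weights(cohort.mesh, 2.25)
per_subject, processed = [], []
for sub in cohort.subjects:
    series = pm.smooth_series(sub.series, cohort.mesh, 2.25, weights=weights)
    series = pm.censor_frames(series, sub.fd, threshold=0.3)
    processed.append(series)
    per_subject.append(pm.subject_seed_maps(series, cohort.group_truth))
templates = pm.average_and_threshold(per_subject, cohort.group_truth.table)

# individualized maps by eta-squared template matching + split-half reliability
mapper = pm.TemplateMatchingMapper(templates, cohort.mesh, sigma_mm=0)
half_maps = []
for sub, series in zip(cohort.subjects, processed):
    labels = mapper(series)
    acc = (labels.labels == sub.truth.labels).mean()
    rec, halves = pm.split_half_reliability(series, mapper, sub.subject_id,
                                            min_retained_minutes=0)
    half_maps.append(halves)
    print(f"{sub.subject_id}: accuracy vs planted truth {acc:.3f}, "
          f"split-half NMI {rec.nmi_within:.3f}")
null = pm.inter_subject_null(half_maps)
print(f"inter-subject NMI: {null.mean:.3f} (5th-95th pct "
      f"{null.p5:.3f}-{null.p95:.3f})")
```

Output:

```
sub-001: accuracy vs planted truth 0.922, split-half NMI 0.952
sub-002: accuracy vs planted truth 0.940, split-half NMI 0.957
sub-003: accuracy vs planted truth 0.932, split-half NMI 0.914
sub-004: accuracy vs planted truth 0.935, split-half NMI 0.914
inter-subject NMI: 0.902 (5th-95th pct 0.871-0.928)
```

Each subject's individualized map recovers ≥ 92 % of its planted topology,
and within-subject split-half similarity exceeds the inter-subject null —
the maps are individual-specific, not just group-typical.

A command-line interface covers the same workflow on TSV/JSON files:

```bash
precimap simulate --subjects 4 --grayordinates 400 --networks 6 \
    --minutes 8 --seed 0 --out cohort/
precimap templates --cohort cohort/ --out templates/
precimap match --series cohort/sub-001_series.tsv --fd cohort/sub-001_fd.tsv \
    --templates templates/ --mesh cohort/mesh.json --out sub-001_labels.tsv
precimap reliability --cohort cohort/ --templates templates/ --out rel/
```

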