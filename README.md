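# netimpact

Network impact scoring of acute ischemic stroke lesions, and the cohort
analysis that links the score to post-stroke cognitive impairment (PSCI).

Roughly half of stroke survivors develop cognitive impairment, and two
infarcts that look similar on routine CT/MRI can have very different
cognitive consequences depending on where they sit in the brain's
structural network. The **network impact score** quantifies this: with a
grey-matter parcellation into regions *r* = 1…R and a fixed network atlas
assigning each region its betweenness centrality *c_r*,

&nbsp;&nbsp;&nbsp;&nbsp;*p_r* = proportion of region *r* covered by the lesion,
&nbsp;&nbsp;&nbsp;&nbsp;score = log ( max*_r* *p_r* · *c_r* ).

A lesion in a network hub — a region on many shortest paths — gets a high
score from even partial coverage. The package provides, for researchers in
stroke imaging and vascular cognitive impairment:

* **atlas** — betweenness centrality from a connectome (edge-list or matrix
  CSV) and validated binding of centrality values to parcellation labels;
* **impact** — per-region overlap proportions, the impact vector, the
  max-log reduction, and batch scoring of NIfTI lesion masks with an
  explicit exclusion report for unscorable (extra-atlas) lesions;
* **cognition** — per-assessment PSCI classification from domain
  percentiles or MoCA (impairment = norm-referenced < 5th percentile in
  ≥ 1 domain; ≥ 3 unimpaired domains needed to exclude), recovery/decline
  transitions against the < 90-day baseline, post-stroke interval strata,
  and prevalence arithmetic;
* **stats** — repeated-measures logistic association via GEE (AR(1)
  working correlation, robust sandwich CIs), interval-stratified and
  transition logistic models, with the standard covariate set (age per
  decade, sex, education, prior stroke, infarct volume per 10 mL, site);
* **synthetic** — a fully seeded generator of parcellations, hub-structured
  connectomes, lesion masks and longitudinal outcomes with known
  generative coefficients, so the entire pipeline is testable offline;
* **io / cli** — NIfTI and CSV I/O, YAML-configured end-to-end runs.

## Worked example

```python
import numpy as np
from netimpact import (Connectome, betweenness_centrality,
                       bind_centrality, score_lesion)

# a 5-region connectome (node_i, node_j, weight)
edges = [(1,2,2.0), (1,3,1.0), (2,3,1.0), (2,4,2.0), (3,4,1.0), (4,5,2.0)]
cent = betweenness_centrality(Connectome.from_edges(edges), weighted=True)
print(cent.to_dict())        # {1: 0.0, 2: 2.0, 3: 0.0, 4: 3.0, 5: 0.0}

# a toy parcellation (5 slabs) and a lesion straddling regions 4 and 5
parc = np.zeros((10, 10, 10), dtype=np.int32)
for r in range(5):
    parc[2*r:2*r+2, 2:8, 2:8] = r + 1
lesion = np.zeros_like(parc, dtype=bool)
lesion[6:9, 3:7, 3:7] = True

print(score_lesion(lesion, bind_centrality(parc, cent)))
# NetworkImpactScore(raw=1.3333333333333333,
#                    log_score=0.28768207245178085, argmax_region=4)
```

The lesion covers 44 % of region 4 (centrality 3) and 22 % of region 5
(centrality 0), so the maximal regional impact is 0.444 × 3 ≈ 1.33 and the
patient's score is ln 1.33 ≈ 0.288, attributed to region 4. Region 5's
larger *absolute* overlap contributes nothing — it is not a hub.

A full synthetic study, scored, classified and modelled end to end:

```bash
netimpact run --seed 1 --out results/demo     # writes scores.csv,
#   psci_long.csv, transitions.csv, models/*.json, run_log.json, truth.json
```

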