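# zooprior

Semi-quantitative prioritization of zoonotic diseases for One Health
collaboration — a scriptable, tested implementation of the
AHP-plus-decision-tree workflow used when human and animal health agencies
must agree on a ranked disease list without comprehensive prevalence data.

## Who this is for

Public-health and veterinary epidemiologists (or the facilitator of a joint
prioritization workshop) who need to turn three inputs into a transparent
ranked list of zoonoses:

1. a **configuration**: 5–9 agreed criteria, one categorical question per
   criterion with a binomial or ordinal answer scale, and a list of
   ~15–30 diseases (`config.yaml`);
2. **pairwise judgments**: each participant's Saaty-scale comparisons of
   every criterion pair (`judgments/<participant>.csv`);
3. an **answer table**: each disease's answer to each question
   (`answers.csv`).

## The method

**Criterion weighting (Analytic Hierarchy Process).** Participant *k*'s
judgments form a positive reciprocal matrix `A` with `A[i,j]` the judged
importance of criterion *i* over *j* on the 1/9…9 scale. The criterion
priorities `p` are the normalized principal right eigenvector of `A`
(`A p = λ_max p`, `Σ p_i = 1`); judgment coherence is summarised by the
consistency ratio `CR = CI / RI(n)` with `CI = (λ_max − n)/(n − 1)` and
`RI(n)` the expected CI of random Saaty-scale matrices (CR > 0.1 warns,
never rejects). The group is merged by the element-wise geometric mean of
the individual matrices (AIJ; arithmetic mean of individual priorities,
AIP, is available). The ranked criteria then receive **sequential integer
weights**: the top criterion of *n* gets weight *n*, the next *n − 1*,
down to 1.

**Disease scoring (weighted decision tree).** Every disease traverses the
criteria in descending weight order. A binomial answer scores `s ∈ {0, 1}`
(the designated full-score answer gets 1); an ordinal answer at 1-based
position *k* of *m* categories scores `s = k/m`. Each node contributes
`q = w·s`; the total `T = Σ q` is normalized against the maximum observed
total, `N = T / T_max`, and the diseases are ranked by `T` (ties share a
rank). Per-question traces make every number auditable.

A seeded synthetic-data module generates whole exercises (latent criterion
importances distorted by log-normal judgment noise, categorical answer
models) for robustness experiments such as rank-recovery curves.

## Worked example

The package ships a complete fictitious exercise (`fixture_country_x`):
5 criteria, 10 participants, 20 zoonoses. Write it out and run the full
pipeline:

```python
from pathlib import Path
from zooprior import config_io, synth

config, judgments, answers = synth.fixture_country_x()
d = Path("demo"); d.mkdir()
config_io.save_config(config, d / "config.yaml")
config_io.save_judgments(judgments, d / "judgments")
config_io.answers_to_frame(answers, config).to_csv(d / "answers.csv", index=False)
```

```
$ zooprior run --config demo/config.yaml --judgments demo/judgments \
               --answers demo/answers.csv --out demo/results
criteria ranking (group CR = 0.0000):
  severity: weight 5 (priority 0.3333)
  bioterrorism: weight 4 (priority 0.2667)
  economic: weight 3 (priority 0.2000)
  collaborate: weight 2 (priority 0.1333)
  epidemic: weight 1 (priority 0.0667)
ranked 20 diseases (T_max = 13.3333)
  1. Highly pathogenic avian influenza: T = 13.3333, N = 1.0000
  2. Trypanosomiasis: T = 11.3333, N = 0.8500
  2. Plague: T = 11.3333, N = 0.8500
  2. Hantavirus infection: T = 11.3333, N = 0.8500
  2. Nipah virus infection: T = 11.3333, N = 0.8500
```

The group's merged judgments rank *severity of illness in humans* first
(weight 5) down to *epidemic potential* (weight 1). For rabies the ranked
report (`demo/results/ranked.csv`) shows

```
rank,disease,total_score,normalized_score,q_severity,q_bioterrorism,q_economic,q_collaborate,q_epidemic
13,Rabies,8.000000,0.600000,5.000000,0.000000,0.000000,2.000000,1.000000
```

i.e. severity answered "yes" (1 × 5 = 5), bioterrorism and economic burden
"no" (0), laboratory capacity "both" (the top of 3 ordinal categories,
3/3 × 2 = 2) and epidemic potential "yes" (1 × 1 = 1): total weighted
score 8, normalized to 0.60 against the top disease's 13.33. Per-question
traces land in `demo/results/traces.json`, the group weights in
`demo/results/weights.json`, and a manifest with input digests in
`demo/results/manifest.json`.

`zooprior simulate --out dir/` generates a synthetic exercise (optionally
from a YAML spec controlling criteria/participants/diseases, latent
criterion importances, judgment noise and answer models);
`zooprior.synth.rank_recovery_probability` estimates how often a panel of
noisy judges recovers a known criterion ranking.

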