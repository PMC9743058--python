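# broodtrack

Breeding-stage inference for tagged waders from GPS revisitation patterns.

## The problem

Eurasian Curlew (*Numenius arquata*) — like many declining, cryptic,
disturbance-sensitive ground-nesting birds — are very hard to monitor in the
field: nests are hidden, chicks are precocial and mobile within hours of
hatching, and every monitoring visit risks desertion or attracting predators.
Yet breeding outcomes are exactly what conservation planning needs, because
population declines in this species are driven by low productivity.

`broodtrack` turns 15-minute GPS tag data into per-bird breeding biology with
no further field visits:

* per-bird **stage timelines** — pre-breeding, incubation, chick guarding,
  post-breeding — with stage changes resolved to a few hours,
* **nest coordinates** for every incubation attempt,
* **attempt fates** (hatched / failed / right-censored at tag loss) and the
  cohort bookkeeping built on them,
* a **daily nest survival rate** (DSR) with profile-likelihood CI,
* a **sampling-schedule sensitivity** analysis (how much can a tag duty-cycle
  before stages become unreadable), and
* a stage-structured **track simulator** with ground truth, so the whole
  pipeline is testable end to end without any field data.

## The method

The core statistic is *revisitation*. For each relocation taken as a focal
point, the trajectory's visits to the closed disc of radius *R* = 20 m around
it (the tags' error scale) are the maximal intervals the piecewise-linear
path spends inside; entry/exit instants are interpolated where a segment
crosses the circle. The histogram of per-fix visit counts over a time window
is a behavioural fingerprint:

* **incubation** — bimodal: a single-visit foraging peak plus a nest focus
  revisited tens to hundreds of times per week (both sexes share incubation);
* **chick guarding** — a sloped mid-range profile: many places visited a few
  times each around a slowly drifting brood, with no dominant focus;
* **non-breeding movement** — dominated by places visited exactly once.

`broodtrack` quantifies those shapes as five window features (proportion of
single-visit fixes, dominant-focus share, 2–10-visit mass, normalised maximum
visit count, daily-centroid drift in m/day) and classifies calendar weeks by
a transparent rule cascade. Stage boundaries are then refined with rolling
3-day windows (day resolution) and finally with 6-h nest-occupancy blocks
(hour resolution); hatches are told from failures by whether the activity
centre drifts slowly away from the nest (mobile brood) or scatters after a
displacement. Nests are located by K-means clustering of the top 20% most
revisited fixes, taking the highest-support centroid.

Attempt fates feed the classic exposure-day survival estimator: with *f*
failures over *E* nest-days, DSR = 1 − *f*/*E*, period success = DSR^28 for
a 28-day incubation, with a profile-likelihood 95% CI. Censored and hatched
attempts contribute exposure only.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 23 birds, study-shaped cohort
python analysis/02_revisit_profiles.py    # weekly profile histograms
python analysis/03_stage_timelines.py     # stage inference vs truth
python analysis/04_breeding_outcomes.py   # attempts, fates, DSR
python analysis/05_sampling_sensitivity.py
```

Step 02 prints, for one simulated breeder (the profile fingerprints):

```
week 2019-04-15: 672 fixes, 530 single-visit, max revisits 5      <- pre-breeding
week 2019-04-22: 672 fixes,  58 single-visit, max revisits 221    <- incubation
week 2019-05-20: 672 fixes,  52 single-visit, max revisits 45     <- chick guarding
week 2019-05-27: 672 fixes, 301 single-visit, max revisits 20     <- brood loss -> post

```

Step 03 scores the inferred timelines against simulator truth:

```
week-label agreement on homogeneous weeks: 76/76 (100.0%)
transition timing: median 1.5 h, 90th pct 3.5 h over 49 changes
```

and step 04 prints the two outcome ledgers side by side — the simulated
cohort as inferred, and the packaged study-cohort fixture (23 tracked birds,
25 nesting attempts transcribed from the published per-bird tables):

```
--- study-cohort fixture ---
  23 birds: 6 non-breeders (26%), 25 attempts, 30% renested
  incubation failures 16/25 (64%); hatched: 18% of breeders, 13% of all birds
  daily nest survival 0.9456 (95% CI 0.916-0.968; 16 failures / 294 exposure days)
```

The same operations are available as a CLI (`broodtrack --help`) with
subcommands `clean`, `revisits`, `classify`, `nests`, `outcomes`,
`survival`, `downsample-eval`, `simulate` and `summarize`.

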