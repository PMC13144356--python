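# whistlekit

Identification, unsupervised classification and characterization of
**repeated stereotyped whistle types** in delphinid recordings — the kind of
analysis used to ask whether free-ranging dolphins (e.g. rough-toothed
dolphins, *Steno bredanensis*) produce recurring, possibly
identity-bearing tonal calls.

It is written for bioacousticians who have single-channel recordings (or
want fully controlled synthetic ones) and need a reproducible, scriptable
version of the usual workflow: extract whistle contours from spectrograms,
sort them into types, quantify how well independent categorizations agree,
and describe the temporal and acoustic structure of the repeated types.

## What it computes

- **Contour extraction** under the standard whistle definition: tonal
  traces >= 100 ms, fragments closer than 200 ms with a continuous
  frequency pattern merged into one contour, qualitative SNR classes
  (high / medium / low) quantified as peak-over-noise excess.
- **DTW contour similarity**: aligned frequencies score
  `100·min(f,g)/max(f,g)`; similarity is the mean local score along the
  best warp path under a slope constraint (warp factor W = 3 lets a
  contour stretch or compress up to 3x). Exact, deterministic, verified
  against exhaustive path enumeration.
- **Adaptive-resonance categorization** (vigilance 96.00, warp 3, bias
  1e-6, learning rate 0.1, max 100 iterations): contours join the
  best-activated category whose reference contour they match at or above
  vigilance, otherwise found a new one; references are running
  warp-averages of their members. Runs globally or per visual type
  ("sequenced").
- **Agreement statistics**: confusion tables, dominant-category agreement
  (`100·max(split)/n`), Hungarian label-matched pairwise agreement,
  Cohen's and Fleiss' kappa, outlier-judge flagging.
- **Bout / IWI statistics**: bouts are >= 3 successive same-type whistles
  with every onset-to-onset gap <= 30 s; inter-whistle intervals are
  summarized with the standard [0.3, 4) / [4, 10) / [10, 60] s classes and
  a 1-s histogram; cross-day occurrence tables.
- **Acoustic parameters + PCA**: W_dur, F_min, F_max, F_start, F_end,
  F_range, F_mean per contour; correlation-matrix PCA with Kaiser
  retention (eigenvalue > 1).
- **Ground-truth synthesis**: stereotyped contour templates (upsweeps,
  downsweeps, stepped, multi-inflection, flat) with duration warping and
  frequency jitter, lognormal IWI bout timing, background singleton
  whistles, and FM-tone audio rendering — so every stage is testable
  end-to-end without field data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from whistlekit import (RepertoireSpec, generate_repertoire, run_global,
                        pairwise_agreement, iwi_summary)
from whistlekit.bouts import type_timelines

spec = RepertoireSpec(n_types=6, exemplars_per_type=(5, 15),
                      background_whistle_rate=0.0, seed=4)
ds = generate_repertoire(spec)
print(f"{len(ds.contours)} whistles, {len(ds.truth.label_set)} planted types")

res = run_global(ds.contours)
print(f"{len(res.categories)} automatic categories, converged={res.converged}")
print(f"agreement with truth: {pairwise_agreement(ds.truth, res.partition):.1f}%")

onsets = {cid: o for ev in ds.timeline.values() for cid, o in ev}
days = {cid: ds.contours[cid].day_label for cid in ds.contours.ids()}
series = type_timelines(ds.truth, onsets, days)
iwis = np.concatenate([np.diff(v) for v in series.values() if len(v) > 1])
s = iwi_summary(iwis)
print(f"IWIs <= 60 s: n={s.n_le_60s}, mean {s.mean_s:.1f} s, "
      f"classes {s.pct_0p3_to_4:.0f}/{s.pct_4_to_10:.0f}/{s.pct_gt_10:.0f}%")
```

prints

```
59 whistles, 6 planted types
6 automatic categories, converged=True
agreement with truth: 100.0%
IWIs <= 60 s: n=50, mean 6.5 s, classes 42/38/20%
```

The categorizer recovers all six planted types exactly (a consequence of
the generator's separability contract: same-type exemplars stay above the
96 % vigilance under warp 3, different types stay below it), and the
interval statistics reflect the truncated-lognormal bout timing the
generator plants.

## Command line

```sh
whistlekit --seed 1 --outdir out run-all        # simulate -> extract ->
                                                # categorize -> agree ->
                                                # bouts -> features
whistlekit --config run.json categorize --mode sequenced --vigilance 96 --warp 3
```

Every stage writes CSV/TSV/JSON artifacts (contour tables, Raven-style
selection tables, assignment and reference-contour tables, confusion and
heatmap tables, bout and IWI summaries, PCA loadings/scores) stamped with
the config hash and seed; a re-run with the same seed is byte-identical.

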