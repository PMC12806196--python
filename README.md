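# moltsucc

Analysis toolkit for postmolt gut-microbiome succession in crustaceans.

When a crab molts, its gut bacterial community is disturbed and reassembles
over the following days, and each gut segment (foregut, midgut, hindgut)
follows its own trajectory. `moltsucc` implements the statistical pipeline
for studying that recovery from 16S ASV count tables sampled at fixed hours
postmolt against a premolt control (CK):

* **Turnover** — ASVs *emerged* (absent at 0 h, present later) or *lost*
  (present only premolt), and *enriched*/*depleted* ASVs by Wilcoxon
  rank-sum + Benjamini–Hochberg with a fold filter.
* **Diversity & dissimilarity** — richness, Shannon entropy, Bray–Curtis
  d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), mock "mixed gut" samples built by summing
  a crab's segment counts, distance-decay regression with a permutation
  test, and segment-versus-whole linear relationships.
* **Tipping points** — a continuous two-segment fit
  y = a + b·t + c·(t−τ)₊ of the dissimilarity-to-baseline trajectory, τ
  chosen by grid search and tested against a straight line with a residual
  bootstrap, so the estimated stabilization time is continuous in hours.
* **Co-occurrence networks** — Spearman + BH thresholded graphs with the
  standard attribute panel, random-removal robustness ("network
  stability"), and single-node vulnerability via global efficiency.
* **Staging & key taxa** — random-forest discrimination of early (≤ 24 h)
  vs late (≥ 48 h) stages with a leakage-free ten-fold CV error curve over
  importance-ranked panels, crab-weight association, and partition of the
  community into early/late/general clusters with stability, abundance, and
  richness panels.
* **Source tracking** — an EM multinomial-mixture over named source
  habitats (carapace surface, rearing water, gill, hepatopancreas) plus an
  explicit *unknown* component, applied to whole sinks, emerged/enriched
  subsets, and single ASVs.
* **Stability & function** — average variation degree (AVD) community
  stability with index 1/(1+AVD), averaging-style multifunctionality from
  pathway z-scores, and taxon–function Spearman screens. Pathway tables
  (e.g. PICRUSt2 output) are consumed, never computed.

A synthetic-community generator with planted, machine-readable ground truth
(breakpoints, emerged/lost/enriched/stage-indicator taxa, source mixtures,
taxon–pathway links) makes every stage testable without any sequencing
data; see `docs/methods.md` for the models and their assumptions.

## Worked example

```python
import moltsucc as m
from moltsucc.synthetic import SyntheticSpec, generate
from moltsucc.tipping import dissimilarity_to_baseline, fit_breakpoint
from moltsucc.turnover import classify_presence

spec = SyntheticSpec(seed=42)          # 3 segments x (8 h postmolt + CK) x 6 crabs
table, metas, taxonomy, truth = generate(spec)
rel = m.to_relative(table)

gut = [x.sample_id for x in metas if x.habitat in ("foregut", "midgut", "hindgut")]
ts, vs = dissimilarity_to_baseline(rel.select_samples(gut), metas)["midgut"]
fit = fit_breakpoint(ts, vs, grid_step=0.1, n_boot=199, seed=42)
print(f"midgut tipping point: {fit.tau:.1f} h "
      f"(95% CI {fit.ci_tau[0]:.1f}-{fit.ci_tau[1]:.1f}, p = {fit.p_value:.3f})")

ids = lambda h, t: [x.sample_id for x in metas
                    if x.habitat == h and not x.is_premolt_ck and x.time_h == t]
calls = classify_presence(table.select_samples(ids("midgut", 0.0)),
                          table.select_samples(ids("midgut", 24.0)))
found = set(calls.index[calls == "emerged"])
print(f"emerged ASVs at 24 h: {len(found)} detected, "
      f"{len(found & set(truth.emerged))} of {len(truth.emerged)} planted")
```

prints

```
midgut tipping point: 27.7 h (95% CI 21.1-31.2, p = 0.005)
emerged ASVs at 24 h: 66 detected, 49 of 50 planted
```

The breakpoint test rejects the straight-line model (p = 0.005) and places
the stabilization time in the mid-twenties of hours — the planted hinge is
at 24 h, and the point estimate sits a few hours above it because the
planted enrichment onset at 24 h adds extra compositional change on top of
the smooth drift (the 95% CI covers the truth). The presence classifier
recovers 49 of the 50 planted emerged ASVs; the extra detections are rare
taxa that genuinely crossed the detection threshold as the community
drifted, i.e. real turnover rather than classifier error.

## Command line

Every stage is also a `moltsucc` subcommand over plain TSV/JSON files:

```bash
moltsucc simulate --seed 7 --out sim/          # four TSVs + ground_truth.json
moltsucc tipping --counts sim/counts.tsv --meta sim/metadata.tsv --out fits.json
moltsucc run-all --config run.yaml             # full pipeline + report.json
```

`run-all` executes turnover → diversity/mixed gut → tipping points →
staging/clusters → networks → stability/function → source tracking, writes
per-stage artifacts plus a report with seeds and input checksums, and with
`--resume` skips the run when config and inputs are unchanged. Exit codes:
0 ok, 1 input error, 2 stage failure.

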