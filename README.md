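# orgdyn

Quantitative analysis of **organelle fission, morphology and mobility**
in live-cell fluorescence time-lapses, with a synthetic ground-truth
generator that makes every stage testable without microscopy data.

The package is built for experiments that ask whether ER-associated actin
(labelled by an ER-targeted actin nanobody, "AC-ER") marks the sites
where endosomes, lysosomes and mitochondria divide, and how perturbing an
ER-anchored actin regulator changes organelle shape and movement.  It
provides, as an importable library:

* **`orgdyn.synthgen`** — simulated multi-channel time-lapses (diffusing
  organelles, scheduled fissions, kiss-and-run events, an AC-ER channel
  with configurable site enrichment over background, camera noise) with
  exhaustive ground truth;
* **`orgdyn.segmental`** — vesicle segmentation (rolling-ball background
  subtraction → despeckle → contrast stretch → median → moments
  threshold → 0.06 µm² size filter → marker-controlled watershed) and
  mitochondrial skeleton morphometrics (adaptive threshold, skeleton
  length, branches per µm);
* **`orgdyn.fissionscan`** — label-lineage fission detection with the
  persistence rule (single parent ≥ 30 s before the split, daughters
  separate ≥ 30 s after; re-merging "kiss-and-run" events excluded) and
  marker scoring at event sites;
* **`orgdyn.chancestat`** — the observed-vs-"by chance" framework:
  chance probability from mask overlap, 2×2 observed/expected tables,
  an exact Fisher test (plus a one-sample binomial alternative), the
  chi-squared curve comparison, per-cell aggregation and one-way ANOVA;
* **`orgdyn.mobility`** — deterministic gated nearest-pair tracking with
  mean straight velocity (displacement ÷ duration, ≥ 10 s tracks), and a
  segmentation-free first-frame Manders autocorrelation mobility curve;
* **`orgdyn.pipeline` / `orgdyn` CLI** — end-to-end orchestration with a
  single seed and schema-stable CSV/JSON outputs.

## The statistics at the core

For `n` scored fission events of which `k` show AC-ER at the site, the
null ("by chance") probability is the fraction of the organelle mask
overlapped by the top-25 % AC-ER mask,

&nbsp;&nbsp;&nbsp;&nbsp;`p_chance = ID(organelle ∩ AC-ER) / ID(organelle)`,

and the comparison is Fisher's exact test on
`[[k, n − k], [round(p·n), n − round(p·n)]]`.  Mobility is summarised by
the mean straight velocity `‖x_end − x_start‖ / duration` per track and
by the decay of `½(M1 + M2)` Manders coefficients between frame 0 and
frame *t*; condition curves are compared with
`X² = Σ_t (ȳ_A − ȳ_B)² / (SEM_A² + SEM_B²)` on `df = #timepoints`.
See `docs/methods.md` for assumptions, parameter defaults and caveats.

## Worked example

`examples/04_observed_vs_chance.py` simulates a movie with strong AC-ER
enrichment (95 % of fission sites painted) over a 20 % background,
detects events from the label lineage, scores the rendered AC-ER channel
and runs the observed-vs-chance comparison:

```
$ python examples/04_observed_vs_chance.py
events scored: 60
observed AC-ER presence: 100.0%
chance overlap estimate: 20.3%
contingency table (rows observed/expected): [[60, 0], [12, 48]]
Fisher exact p = 3.18e-22
one-sample binomial p = 2.84e-42
```

60 events were detected (every scheduled, rule-compliant split); AC-ER
was found within 0.25 µm of every site during the 30 s before each
split, against a measured chance level of ~20 % — the marker's presence
at fission sites is far beyond coincidental overlap.  The other examples cover dataset generation,
segmentation accuracy, fission-rule behaviour, velocity comparisons and
the autocorrelation readout; each prints the numbers it computes and a
line on what they mean.

A shell entry point mirrors the library:

```bash
orgdyn simulate --seed 1 --out ds/        # synthetic dataset + truth
orgdyn run-all --seed 1 --out results/    # full pipeline
orgdyn demo                                # enrichment-vs-chance demo
```

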