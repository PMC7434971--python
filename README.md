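# textphase

Analysis pipeline for ordered corpora of short documents: map each
document into a correspondence-analysis factor space, quantify its
"charge" as the Euclidean norm of its squared-cosine vector, and locate a
phase-transition-like regime shift in that series with dynamic
complexity, recurrence, and time-frequency representations combined by
change-point analysis.

## What it does

1. **corpus_prep** — segment documents into elementary context units,
   tokenise, lemmatise (TSV dictionary), frequency-rank the lemmas, drop
   the top 5%, select the most frequent 10% of the remainder, and build a
   binary document x lemma indicator matrix.
2. **factor_space** — simple correspondence analysis of the indicator
   matrix (SVD of the standardised residuals); per-document squared
   cosines over the first K axes (default K = 10).
3. **affective_charge** — Euclidean distance of each squared-cosine
   vector from the origin; classification against the centroid radius
   (the mean distance); inside/outside counts and percentages.
4. **trend_models** — logistic regression of the labels on time,
   ACF/PACF correlograms, ARIMA(1,1,1) with drift, Ljung-Box residual
   diagnostics (statsmodels-backed).
5. **nonlinear_dynamics** — moving-window dynamic complexity
   (fluctuation x distribution, window 7), unthresholded recurrence
   distance matrix (m = 3, tau = 1), Stockwell-transform time-frequency
   amplitudes.
6. **change_points** — exhaustive single change-point search with a
   least-squares (mean) or Gaussian log-variance cost, thresholds
   calibrated on white noise; per-line matrix CPA with mode aggregation;
   ensemble transition = rounded mean of the per-representation indices.
7. **synthetic_data** — factor-topic corpus generator with an injected
   polarization shift, and an integrated-ARMA charge-series generator
   with an innovation-variance shift, so the whole pipeline is testable
   without external data.

## CLI

```sh
# generate a synthetic corpus with a regime shift at document 58
textphase simulate --out corpus/ --seed 1

# full pipeline: corpus -> report.json (exit 3 = no transition detected)
textphase run --corpus corpus/ --out run1/

# individual stages
textphase prep corpus/ --out matrix.tsv
textphase factors matrix.tsv --out fs/
textphase charge matrix.tsv --out charge.tsv
textphase trend charge.tsv
textphase dynamics charge.tsv --out dyn/
textphase detect charge.tsv --cost-kind variance
```

`textphase run` also accepts `--matrix` (skip text stages) or `--series`
(analyse any numeric series), and `--config cfg.yaml` with `RunConfig`
fields. Every run writes its intermediates (lemma matrix, charge series,
complexity profile, recurrence and TFD matrices) plus `report.json` to
the output directory; identical config + seed reproduces the report
byte-identically.

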