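# panelforge

Multi-biomarker panel discovery for case/control plasma proteomics.

Given proteins-by-injections log2-intensity tables for three studies
(training, validation, testing), panelforge:

1. **normalizes** each study (quantile normalization, per study);
2. **intersects** protein identifiers across the three studies;
3. **screens** candidates on the training study with a per-protein nested
   ANOVA (fixed group effect tested against samples-within-groups,
   replicate injections pooled into the residual), keeping raw p < alpha;
4. **enumerates** every N-marker panel from the candidate pool and scores
   each with a from-scratch feed-forward neural network (one hidden layer,
   sigmoid activations, sum-of-squared-errors backpropagation, two-variable
   class encoding). 5-fold cross-validation on the training study selects
   an epoch budget, the network is retrained on the full training study,
   and the panel's figure of merit is its ROC AUC on the validation study;
5. **selects** the panel maximizing validation AUC and assesses it exactly
   once on the untouched testing study (confusion matrix plus sensitivity,
   specificity, precision, accuracy and AUC).

A synthetic-data module generates studies with the assumed variance
structure (random sample effect, random injection effect, residual, plus a
planted set of differential proteins), so the entire pipeline is testable
without any external data.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
confusion-matrix examples, enumeration exhaustiveness, gradient checks
against finite differences, AUC vs. Mann-Whitney pair counting, null
calibration of the screen, end-to-end marker recovery, and the
selection-bias Monte Carlo). The full suite runs in about a minute on one
CPU.

## CLI

```sh
# simulate three studies (A/B/C) into a directory
panelforge simulate --n-proteins 50 --n-informative 5 --effect-size 2.5 \
    --seed 1 --outdir sim/

# quantile-normalize one study's table
panelforge normalize sim/study_A_intensity.tsv normA.tsv

# per-protein ANOVA screen
panelforge screen sim/study_A_intensity.tsv sim/study_A_metadata.tsv \
    --alpha 0.01 --out screen.tsv

# full search: screen + exhaustive panel enumeration + one-shot test assessment
panelforge search \
    --train sim/study_A_intensity.tsv sim/study_A_metadata.tsv \
    --validation sim/study_C_intensity.tsv sim/study_C_metadata.tsv \
    --test sim/study_B_intensity.tsv sim/study_B_metadata.tsv \
    --panel-size 5 --alpha 0.01 --pool-cap 10 --seed 1 --outdir out/

# or drive everything from a JSON config (simulation or file paths)
panelforge run --config config.json

# pretty-print the top-ranked panels
panelforge report out/report.json --top 3
```

Outputs: `report.json` (full ranking, machine-readable), `ranking.tsv`
(flat table) and `manifest.json` (seeds + configuration echo sufficient to
re-run the pipeline bit-identically).

The default pool cap (top 10 candidates by p-value) keeps the exhaustive
enumeration desk-scale; a full 32-choose-5 run (201,376 panels) is a
long-running mode — use `--pool-cap 32 --jobs N --checkpoint ckpt.json`.
Per-panel seeds are derived from the global seed and the panel ids, so
parallel and serial runs give identical results.

## Layout

- `src/panelforge/io_model.py` — intensity-matrix / study-design model, TSV I/O, reports
- `src/panelforge/synthetic_data.py` — seeded study simulator with planted markers
- `src/panelforge/preprocess.py` — log2 transform, quantile normalization
- `src/panelforge/anova_screen.py` — nested ANOVA, candidate screening
- `src/panelforge/ffnn.py` — feed-forward network, backprop, cross-validation
- `src/panelforge/metrics.py` — confusion metrics, ROC, AUC
- `src/panelforge/panel_search.py` — exhaustive enumeration, selection, test assessment
- `src/panelforge/pipeline.py`, `src/panelforge/cli.py` — orchestration and CLI
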