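# pparmix

Analysis pipeline for dual-luciferase reporter studies of fatty-acid (FA)
activation of the peroxisome proliferator-activated receptors (PPAR), built
for the question: *when FAs are supplied as mixtures, is the activation they
produce a weighted average of their individual potencies, the sum of them,
or more than the sum — synergy?*

It is aimed at nutrigenomics groups running plate-based transactivation
assays (a PPRE-driven firefly luciferase reporter co-transfected with a
constitutive *Renilla* control): the package takes per-well luminescence
tables, normalizes them to fold-change versus vehicle, fits per-FA
dose–response curves, designs combinatorial mixtures at peak-derived doses,
and scores mixtures against two null models. A seeded plate simulator with
a declared ground truth stands in for raw instrument data and makes every
stage testable against known answers.

## The model

Activation of one well is the ratio *F/R* (firefly over *Renilla*), expressed
as fold-change against the plate's mean vehicle ratio. Per FA, fold-change
is regressed on dose with replicate as a block:

    fold = b0 + b1·d + b2·d² (+ b3·d³) + block(replicate)

and the selected polynomial's maximizer over the tested range is the FA's
**peak dose**. For a mixture of n components, where FAₓ is component x's
activation alone at its peak dose and µMₓ its molarity in the mixture, two
expectations are computed:

* weighted average (one binding pocket, competitive occupancy):
  E_w = Σ FAₓ·µMₓ / Σ µMₓ
* additive (independent contributions): E_a = Σ FAₓ

The %Δ statistic is 100·(measured − E)/E; a mixture is **synergistic** when
measured/E_a > 1. Across a set of mixtures, the adequacy of each model is
the slope *a* of the through-origin regression `actual = a·expected`
(a = Σ e·y / Σ e²) — a slope near 1 identifies the better model.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
plates (six-FA panel, 10-point dose series, n = 4 replicates, 10% well CV,
weighted-average mixture truth; all seeded):

```
python analysis/01_simulate_plates.py
python analysis/02_normalize_wells.py
python analysis/03_fit_dose_response.py
python analysis/04_design_mixtures.py
python analysis/05_score_synergy.py
python analysis/06_compare_groups.py
python analysis/07_operating_characteristics.py
```

`03_fit_dose_response.py` prints the recovered single-FA profiles:

```
  C12:0: linear response, peak 4.20-fold at 500 uM
  C16:0: quadratic response, peak 3.11-fold at 160 uM
  C18:0: quadratic response, peak 3.07-fold at 193 uM
  ...
```

i.e. the laurate-like FA keeps rising to the top dose while the palmitate-
and stearate-like FAs peak between 150 and 200 µM — the estimated peak
doses land within a few µM of the generating truth (500, 158, 190 µM).
`05_score_synergy.py` then scores all 15 pairs and 20 triples:

```
 k    model  slope  n_points
 2 weighted  1.005        15
 2 additive  0.526        15
 3 weighted  0.622        20
 3 additive  0.223        20
```

For pairs the weighted-average slope is ≈ 1 and the additive model
over-predicts by ~2×: the scoring correctly identifies the weighted truth
the data were generated under. The triple rows illustrate a real caveat of
peak-dose scoring at reduced mixture doses (see `docs/methods.md`).
`07_operating_characteristics.py` reports estimator quality, e.g. median
relative peak-dose error 1.0% and type-I rates of 5.2% (dose F-test) and
6.4% (pairwise) at nominal 5%.

The same pipeline is scriptable from a YAML config via the CLI
(`pparmix simulate|analyze|synergy|report --config examples/study.yaml`).

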