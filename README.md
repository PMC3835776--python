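# sarcoma-cea

A two-year Markov cohort cost-utility model of first-line chemotherapy
in advanced soft-tissue sarcoma (ASTS), comparing the
doxorubicin/ifosfamide combination against trabectedin monotherapy for
the publicly funded health systems of Italy, Spain and Sweden. It is
written for health economists and modellers who want a tested, reusable
implementation of this comparison — cohort engine, costing, incremental
analysis and sensitivity analysis — rather than a spreadsheet.

## The model in brief

A 65-year-old cohort enters in progressive disease (PD) and starts
first-line chemotherapy. Over 24 monthly cycles patients move between
PD, complete response (CR), partial response (PR), stable disease (SD)
and death. Response resolves after 3 treatment cycles; responders hold
their state for the median response duration (tunnel states), then
relapse to PD. First-line failures switch to the country's mix of
second-line regimens; second-line failures receive palliative care only.
Background mortality applies everywhere, cancer-related mortality
(calibrated from survival curves by least squares on log-survival) only
in PD. Utilities u(CR)=0.60, u(PR)=0.51, u(SD)=0.43, u(PD)=0.30 accrue
per month; costs accrue in ten categories (drugs at whole-vial
dispensing with BSA 1.8 m², delivery, tests, supportive medication,
toxicity management, palliative care). Year-2 flows are discounted at
3%.

For strategies A (doxorubicin/ifosfamide, reference) and B
(trabectedin):

    ICER = (Cost_A − Cost_B) / (QALY_A − QALY_B)

A is *dominant* when it is both cheaper and more effective. The
probabilistic sensitivity analysis redraws all probabilities/utilities
(beta) and costs/resource quantities (gamma) by method of moments and
reports the probability that A is cost-effective as a function of the
willingness-to-pay threshold λ (net monetary benefit λ·ΔQALY − Δcost).

## Worked example

```
$ sarcoma-cea base --country italy
doxorubicin_ifosfamide: EUR 44,632.1, 0.568 QALYs
trabectedin: EUR 45,304.5, 0.524 QALYs
incremental: EUR -672.4, 0.044 QALYs, ICER EUR -15,303/QALY (dominant)
```

Read: over two years the doxorubicin/ifosfamide strategy costs €672
less per patient and yields 0.044 more QALYs than first-line
trabectedin, so it dominates (the negative ICER with positive QALY gain
means "cheaper and better"). The same command writes the ten-category
cost table (`costs_italy.csv`) and a JSON results record. Other
subcommands: `psa` (CE-plane scatter and acceptability curve), `dsa`
(±20% one-way analysis, tornado order), `calibrate` (hazard fit to
survival points), `synth` (synthetic fixtures).

The same in Python:

```python
import sarcoma_cea as sc

params = sc.load_country("italy")
ref, comp, cea = sc.compare_strategies(params)
print(cea.delta_cost, cea.delta_qalys, cea.quadrant)
# -672.4 0.0439 dominant
```

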