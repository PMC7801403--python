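# clonfate

Barcode lineage-tracing analysis for distinguishing **selection** from
**induction** of mTORC1 signalling states in AML under chemotherapy, with a
stochastic two-state clonal simulator as ground-truth generator.

## The problem

Chemotherapy-surviving AML cells read as mTORC1-high by a degron-based
fluorescent reporter (mVenus intensity is *inversely* proportional to mTORC1
activity). Two mechanisms could explain this shift:

* **selection** — pre-existing mTORC1-high clones preferentially survive;
* **induction** — surviving cells of any ancestry convert into the high
  state (plasticity).

Because lentiviral barcodes (30-nt semi-random weak/strong sequences) are
heritable and each founder cell starts in a single state, the two mechanisms
leave different fingerprints in per-barcode count tables sorted by reporter
gate:

* the **shared-barcode fraction** — barcodes detected in both the mTORC1-high
  (H) and -low (L) gates. Without state transitions every clone is
  mono-state, so selection forces this toward 0; induction keeps it high.
* **cumulative clone-proportion curves** — barcodes ranked by decreasing
  proportion with cumulative proportion plotted; steeper curves (higher Gini
  coefficient) mean fewer clones dominate, i.e. stronger selection. The
  maximum vertical gap between the H and L curves is benchmarked against a
  pooled-resampling bootstrap null.
* the **within-barcode log-odds ratio** for barcodes shared by both gates,

  LOR(b) = ln[(c_H(b)+q)/(D_H+qk)] − ln[(c_L(b)+q)/(D_L+qk)],

  with pseudocount q = 1/2, per-gate depths D and union barcode count k.
  Under induction at stationarity this distribution is symmetric and centred
  at 0.

`clonfate` implements the whole measurement chain: a birth–death–transition
simulator with chemotherapy kill and nutrient-coupled state switching,
synthetic FASTQ / flow-cytometry / FRET / 3-D image generation with ground
truth, barcode extraction and error-correcting collapse, the three statistics
plus a calibrated mechanism classifier, and the reporter quantification rules
(10th-percentile reference gating, mVenus/TdTomato ≥ 0.4 ratio
classification, 3-D Euclidean distance to the bone surface).

## Worked example

Run a scaled-down induction experiment (1,000 barcoded founders, 10-day
engraftment, chemotherapy days 0–5, sampling days 0/5/7) and classify the
mechanism from the sorted count tables:

```python
from clonfate import ExperimentDesign, MechanismSpec, classify_mechanism, run_experiment
from clonfate.config import DEFAULT_RATES

design = ExperimentDesign(
    n_exposed_cells=10_000, infection_prob=0.1, n_transplanted=5_000,
    growth_days=10.0, sampling_days=(0.0, 5.0, 7.0), n_sorted_per_gate=5_000,
    seed=1,
)
traj = run_experiment(design, MechanismSpec("induction"), DEFAULT_RATES)
tables = {}
for (day, gate), counts in traj.sorted_counts.items():
    tables.setdefault(day, {})[gate] = counts
report = classify_mechanism(tables, seed=1)
print(report.per_day[["day", "shared_fraction", "divergence",
                      "divergence_null95", "lor_median", "lor_sign_p",
                      "call"]].round(4).to_string(index=False))
print("mechanism call:", report.call)
```

prints

```
 day  shared_fraction  divergence  divergence_null95  lor_median  lor_sign_p          call
 0.0           0.9038      0.0102             0.0143      0.0000      1.0000     induction
 5.0           0.8758      0.0257             0.0225     -0.0299      0.5453 indeterminate
 7.0           0.8725      0.0110             0.0182      0.0000      0.0927     induction
mechanism call: induction
```

Roughly 90% of detected barcodes appear in both reporter gates at every
timepoint, the H/L cumulative curves stay within the resampling null, and
the within-barcode log-odds are centred at 0 — the induction fingerprint.
Day 5 (mid-chemotherapy) is individually indeterminate here because the
curve gap just grazes its null at this small scale; the per-day calls are
aggregated by majority vote with the day-7 burden nadir breaking ties. A
selection-template run of the same design yields shared fractions of exactly
0 and the call `selection`.

The same pipeline is available from the shell:

```sh
clonfate config-template > config.yaml      # all defaults, commented
clonfate run-all --config config.yaml --seed 7 --out out/
clonfate stats --counts out/count_tables.csv --out out/ --seed 7
```

## Layout

| module | contents |
| --- | --- |
| `clonfate.clonal_sim` | two-state birth–death–transition–kill simulator, library seeding, gate sorting, in-silico experiment runner |
| `clonfate.synth_assets` | synthetic FASTQ reads, cytometry/FRET event tables, 3-D image stacks with ground truth |
| `clonfate.barcodes` | barcode extraction (flank/quality/pattern filters) and greedy Hamming collapse |
| `clonfate.clonestats` | cumulative curves, Gini, shared fraction, log-odds, bootstrap, mechanism classifier, gene-set overlap test |
| `clonfate.reporter_quant` | percentile reference gating, inhibition rate, burden–activity correlation, G0/apoptosis calls, cell detection, distance to bone |
| `clonfate.config` / `clonfate.cli` | validated YAML configuration, sub-seeding, `clonfate` command-line pipeline |

See `docs/methods.md` for the model, calibration and numerical choices.
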