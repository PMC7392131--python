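# cartrake

Selection-bias characterization and correction for loyalty-card
grocery-purchase cohorts: a synthetic cohort generator, a unit-level
multi-margin raking (iterative proportional fitting) weight builder with
trimming and two-phase missing-data handling, RFM loyalty scoring, and
food-group purchase summarization with weighted statistics.

## What it does

Volunteer cohorts recruited through retailer loyalty programs
over-represent some sociodemographic groups (e.g. women, the
higher-educated, the employed) and under-represent others (the youngest
and oldest). `cartrake` quantifies that bias against reference population
margins and corrects it by poststratification weighting:

- **`cartrake.synthetic`** — generates a reference population with
  realistic two-way sociodemographic associations, a logistic consent
  mechanism, questionnaire nonresponse, zero-inflated log-normal
  purchase histories, and a five-category self-reported degree of
  loyalty tied to purchase volume. Everything downstream is testable
  without any external data.
- **`cartrake.margins`** — margin-table I/O, sample cross-tabulation,
  declarative category harmonization, and validation (zero cells,
  category mismatches, empty sample cells).
- **`cartrake.raking`** — the computational core: iterative proportional
  fitting at the unit level over any mix of one-way/two-way margins,
  weight trimming into [0.1, 10], rescaling, and two-phase weighting
  (full margins for complete cases, sex x age only for records missing
  questionnaire variables).
- **`cartrake.rfm`** — recency/frequency/monetary quintile bins and the
  composite score `100*R + 10*F + M` in [111, 555], plus group
  comparisons (ANOVA and Kruskal-Wallis).
- **`cartrake.food_groups`** — product-code -> food-group mapping with
  coverage reporting, per-participant EUR/kg totals and shares, weighted
  quantiles, and weighted-vs-unweighted median [IQR] tables.
- **`cartrake.group_analysis`** — stratified comparisons across the five
  loyalty groups: chi-square for categorical variables, tie-corrected
  Kruskal-Wallis for purchase variables.
- **`cartrake.pipeline`** — end-to-end orchestration with run logging,
  recruitment-flow percentages, and deterministic seeded reruns.

## CLI

```bash
cartrake generate --population-size 50000 --seed 1 --out data/
cartrake rake --sample data/participants.csv --margins m1.csv m2.csv \
    --trim 0.1 10 --total 47045 --tol 1e-7 --out weights.csv
cartrake rfm --transactions data/transactions.csv --ref-date 2018-12-31 --out rfm.csv
cartrake summarize --transactions data/transactions.csv --mapping mapping.csv \
    --weights weights.csv --out table_food.csv
cartrake profile --participants data/participants.csv --rfm rfm.csv --out report/
cartrake run --seed 1 --out run/          # full synthetic pipeline
```

Margin CSVs carry variable names in the header plus a final `count`
column; harmonization files are `variable,from_category,to_category`;
the product mapping is `product_group_code,food_group`.

## Library example

```python
import cartrake as ct

cfg = ct.default_config(population_size=100_000, seed=1)
cohort = ct.simulate_cohort(cfg)

margins = [ct.margin_from_sample(cohort.population, v)
           for v in (["sex", "age_group"], ["sex", "education"], ["children"])]
participants = cohort.participants.set_index("id", drop=False)
result = ct.two_phase_weights(participants, margins, margins[:1])
print(result.converged, result.weights.sum())
```

## Testing notes

The suite pairs every algorithm with an independent brute-force oracle
(`tests/_oracles.py`): unit-level raking against classical cell-level
IPF, cross-tabulation against nested counting loops, Kruskal-Wallis
against an exhaustive permutation enumeration, weighted quantiles
against a cumulative-weight scan. `tests/test_acceptance.py` covers the
acceptance criteria: printed-ratio arithmetic, raking correctness,
end-to-end bias-correction recovery on a 50,000-unit synthetic cohort,
test-statistic calibration, and the RFM contract.
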