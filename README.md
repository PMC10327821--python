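# gscea

Cost-effectiveness model comparing gene-signature-guided (21-gene recurrence
score) adjuvant chemotherapy decisions against standard of care in
HR+/HER2− early breast cancer, from a payer perspective.

The pipeline has two stages, evaluated per patient over a lifetime horizon
(to age 100):

1. **Decision tree** — each of three sub-populations (premenopausal
   node-negative, postmenopausal node-negative, postmenopausal node-positive)
   is split into weighted (RS category × treatment) branches under either the
   test-guided strategy or standard of care.
2. **Markov cohort model** — each branch is propagated through five health
   states (recurrence-free, distant recurrence, AML, CHF, death) on 6-month
   cycles with half-cycle correction; CHF carries an internal tenure split so
   first-year excess mortality applies by time in state. Branch traces are
   valued into discounted costs (nine reporting categories), life-years and
   QALYs, then weight-averaged to stratum and population level and compared
   (ICER / dominance / net monetary benefit at €20,000 per QALY).

Discounting is two-tier (2.5 % per year for the first 30 years, 1.5 %
thereafter). Uncertainty analysis includes one-way DSA (tornado tables),
seeded probabilistic sensitivity analysis with per-parameter RNG streams,
acceptability curves, and a deep-merge scenario runner.

External inputs the configuration does not supply (life table, age-utility
multiplier curve, CHF incidence curve, PSA distributions) are replaced by
synthetic, configurable stand-ins — a Gompertz–Makeham female life table
calibrated to a life expectancy of ~85 years, a linearly declining utility
multiplier, an exponentially age-increasing CHF incidence, and conventional
beta/gamma/lognormal/dirichlet parameter distributions. Absolute results
therefore depend on these stand-ins; the decision-tree arithmetic and all
structural behavior are exact.

## CLI

```bash
gscea run --base-case --output out/          # traces + summary tables
gscea run --config my_config.yaml --no-discount
gscea dsa --base-case --output out/          # tornado_cost.csv, tornado_qaly.csv
gscea psa --base-case --n 5000 --seed 1 --output out/
gscea scenario --base-case --scenario overrides.yaml --output out/
gscea synth --output curves/ --life-expectancy 85
```

All outputs are plain CSV/JSON; every analysis run writes a `run_log.json`
provenance record (config digest, version, options). Configurations are YAML
or JSON documents with sections `population`, `clinical`, `utilities`,
`costs`, `discount`, `settings`; curve inputs may be CSV paths or inline
age→value maps and fall back to the synthetic defaults when omitted. The
embedded base case is available as `gscea.base_case_config()`.

## Python API

```python
from gscea import base_case_config, run_model

result = run_model(base_case_config())
comp = result.population_comparison
print(comp.status, comp.delta_cost, comp.delta_qaly, comp.nmb)
```

## Layout

- `src/gscea/parameters.py` — parameter types, config loading/validation, embedded base case
- `src/gscea/synthetic_inputs.py` — life table, age curves, PSA distributions
- `src/gscea/conversions.py` — hazard-scale probability arithmetic, discounting
- `src/gscea/decision_tree.py` — branch allocation and CT probabilities
- `src/gscea/cohort_engine.py` — transition matrices, cohort traces, half-cycle correction
- `src/gscea/valuation.py` — costs by category, LY/QALY valuation
- `src/gscea/outcomes.py` — aggregation, ICER/NMB comparison, deterministic pipeline
- `src/gscea/uncertainty.py` — DSA, PSA, CEAC, scenario runner
- `src/gscea/cli.py` — command-line interface
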