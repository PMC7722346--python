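# linetester

Analysis toolkit for multi-environment **line × tester** maize trials run
under contrasting (drought / rain-fed) conditions:

- **trial I/O and validation** (`linetester.core`) — long-format CSV plot
  data with strict bounds/duplicate checking; missing cells stay missing.
- **synthetic trial generator** (`linetester.simulate`) — balanced trials
  with additive GCA, SCA, G×E and plot-error variance components, correlated
  secondary traits on a latent Gaussian scale, a configurable drought yield
  ratio, and a full ground-truth record for recovery testing.
- **means, ANOVA, variance components** (`linetester.means_anova`) —
  least-squares genotype means, sequential balanced ANOVA
  (E / Rep(E) / Block / G / G×E / Error), expected-mean-squares variance
  components, hybrid-mean repeatability and CV%.
- **combining ability** (`linetester.combining`) — GCA/SCA effects with
  standard errors and t-test stars, the line/tester/line×tester mean-square
  partition, and the GCA-over-SCA proportion (interaction-corrected
  components, pooled over lines and testers).
- **base index** (`linetester.index`) — standardized multi-trait drought
  tolerance index `2·z(yield) + z(epp) − z(asi) − z(pasp) − z(easp) −
  z(sgc)` with deterministic best/worst selection.
- **heterotic grouping** (`linetester.heterotic`) — rule-based tester
  classification from SCA effects, significance flags and testcross means,
  with per-line rule traces; a digitized testcross table ships as a fixture.
- **GGE biplot geometry** (`linetester.gge`) — environment-centered SVD,
  singular-value partitioning, which-won-where hull/sectors/winners, and
  average-environment-axis mean/stability/ideal-genotype rankings (tables,
  not figures).
- **pipeline + CLI** (`linetester.pipeline`, `linetester.cli`).

## CLI

```sh
linetester simulate --seed 1 --out trial.csv --truth truth.csv
linetester anova trial.csv --trait yield --scope drought --out anova.csv
linetester combining trial.csv --trait yield --condition drought \
    --out gca_sca.csv --anova-out ca_anova.csv
linetester index trial.csv --condition drought --out index.csv
linetester classify --out groups.csv          # packaged testcross fixture
linetester gge grid.csv --out-prefix gge      # genotype x environment grid
linetester full --seed 1 --out bundle/        # whole pipeline
```

`linetester full` accepts a YAML config (`--config`) with an `input` path or
a `generator` section plus `traits`, `alpha`, `n_best`, `n_worst`,
`svp_mode`.

## Notes

- Balanced-only estimators (closed-form ANOVA, the line × tester mean-square
  partition) refuse unbalanced data explicitly; genotype means fall back to
  an additive least-squares adjustment, and incomplete line × tester grids
  are fitted by constrained two-way least squares and flagged `ls`.
- Variance components use the expected-mean-squares method of moments,
  which coincides with REML on the balanced complete layouts the generator
  produces; negative estimates are truncated to zero with a warning.
- Published mean squares, repeatabilities, CVs, GCA effect tables, index
  values and biplot coordinates from the motivating study cannot be
  reproduced exactly without its undeposited plot-level data; the test
  suite covers those quantities with simulation bands and identities
  instead (see `tests/test_acceptance.py`).
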