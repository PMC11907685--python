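# gtbart

Bayesian additive regression trees (BART) for **group testing data**:
estimate an individual-level probability-of-disease surface and assay
sensitivity/specificity from pooled, possibly misclassified binary test
responses.

The model is a probit BART,

```
P(Y_i = 1 | x_i) = Phi(eta(x_i)),    eta = offset + sum of K regression trees,
```

observed only through pool-level tests `Z_j` on index sets of individuals,
with per-stratum sensitivity `Se(l)` and specificity `Sp(l)` (known, or
estimated under beta priors). Inference is a full Gibbs sampler built on
two-stage data augmentation: latent true statuses `Y~`, then truncated-normal
latents `omega` (Albert–Chib), with backfitting Metropolis–Hastings updates
for the trees and conjugate beta updates for the accuracies. A probit GLM
comparator shares the identical augmentation scan with a conjugate normal
coefficient draw in place of the trees.

Protocol simulators reproduce the standard designs: individual testing (IT),
master pool testing (MPT), and two-stage Dorfman testing (DT: master pools,
then individual retests of every member of an observed-positive pool), with
stratum-specific misclassification and three built-in generating models
(M1 highly non-linear, M2 linear, M3 non-linear with an interaction).

## Layout

| module                | contents                                                        |
|-----------------------|-----------------------------------------------------------------|
| `gtbart.group_data`   | `GroupTestingData`, `AssayAccuracy`, validation, pool status    |
| `gtbart.protocol_sim` | generating models, pool assignment, IT/MPT/DT simulators        |
| `gtbart.tree_model`   | trees, regularization prior, proposals, integrated likelihood   |
| `gtbart.gibbs`        | latent-status scan (numba), omega draws, backfitting, `run_chain` |
| `gtbart.glm`          | probit GLM comparator (`run_glm_chain`)                         |
| `gtbart.summaries`    | inclusion proportions, AUC, coverage, simulation-study driver   |
| `gtbart.io`           | CSV dataset formats, posterior store, manifests                 |
| `gtbart.cli`          | `gtbart simulate / fit / summarize / study`                     |

## CLI

```bash
# simulate a Dorfman dataset (writes ds.covariates.csv, ds.tests.csv, ds.truth.csv)
gtbart simulate --model M3 --n 1000 --protocol DT --se 0.95 --se 0.98 \
       --sp 0.98 --sp 0.99 --seed 1 --out ds

# fit the BART sampler; accuracy config is a YAML/JSON list per stratum
cat > acc.json <<'EOF'
[{"se": 0.5, "sp": 0.5, "known": false}, {"se": 0.5, "sp": 0.5, "known": false}]
EOF
gtbart fit --data ds --model bart --trees 20 --burn 1000 --keep 1000 \
       --seed 2 --accuracy-config acc.json --store-trees --out post/

# summaries: predictions, accuracy intervals, inclusion proportions
gtbart summarize --posterior post/ --query-grid grid.csv --out report/

# replicated simulate-fit-evaluate study from a config file
gtbart study --config study.yaml --out study.csv
```

Every run writes a `manifest.json` (config echo + seed + version) next to its
outputs; datasets and posterior stores are plain CSV/JSON and round-trip
exactly.

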