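# logsumreg

Sparse penalized linear regression for QSAR descriptor selection.

In quantitative structure–activity relationship (QSAR) modelling a
compound is encoded by hundreds to thousands of numeric molecular
descriptors, of which only a handful are genuinely related to the
measured biological activity. `logsumreg` selects that handful by
fitting

    min_b  (1/2n) ||y − X b||²  +  λ Σ_j log(|b_j| + ε),        0 < ε < λ,

a log-sum penalized multiple linear regression. The log-sum penalty is
a tight non-convex surrogate of the L0 count: it zeroes irrelevant
descriptors aggressively while barely shrinking the ones it keeps. The
solver is cyclic coordinate descent in which each coordinate update is
a closed-form univariate *log-sum thresholding* operator

    D(w, λ, ε) = sign(w) (c1 + √c2)/2   if c2 > 0,   else 0,
    c1 = |w| − ε,   c2 = c1² − 4(λ − |w| ε),

applied to the partial-residual correlation w_j of each descriptor.
Five comparator penalties are implemented behind the same interface:
L1 (lasso), elastic net, SCAD, MCP and L1/2 (half thresholding). The
package also ships the support-recovery simulation benchmark used to
compare the six methods and the standard QSAR evaluation metrics
(R²/RMSE on training and test splits, leave-one-out Q² and RMSE_CV).

Intended users: cheminformaticians and method developers who have a
descriptor table (rows = compounds, columns = named descriptors plus
one activity column) and want a small, interpretable descriptor subset
with honest validation numbers.

## Worked example

Simulate a benchmark dataset with a known 20-descriptor support
(p = 2000 descriptors, n = 200 compounds, correlated columns 2–6,
noise σ = 0.9), tune λ by 5-fold cross-validation and inspect the
selection:

```python
from logsumreg import SimulationConfig, generate, tune, PenaltySpec

sim = generate(SimulationConfig(n=200, p=2000, rho=0.4, sigma=0.9, seed=1), replicate=1)
path = tune(sim.data, PenaltySpec("logsum"), n_lambda=50, n_folds=5, seed=7)
best = path.best_fit
print("lambda:", round(path.best_lambda, 4))
print("selected:", best.n_selected)
print("true positives:", len(set(best.selected) & set(sim.true_support)))
```

Output:

```
lambda: 0.0117
selected: 21
true positives: 20
```

All 20 preset descriptors are recovered with one false positive out of
2000 candidates. The same flow works on a real descriptor table from
the command line:

```bash
logsumreg evaluate table.csv --activity pIC50 --penalty logsum --seed 1 --out reports/
```

which performs a seeded 80/20 split, tunes λ on the training set,
and prints one row of the six metrics, e.g.

```
method  R2train  RMSEtrain  Q2LOO   RMSECV  R2test  RMSEtest  n_selected
logsum  1.0000   0.0124     1.0000  0.0171  1.0000  0.0206    20
```

(numbers from a noiseless simulated 40-descriptor table — the same
setup as `tests/test_cli.py::test_qsar_pipeline_noiseless_recovers_signal`;
real tables land wherever their signal-to-noise puts them). Other
verbs: `logsumreg simulate` writes replicate CSVs, `logsumreg fit`
fits a single model (fixed or auto-tuned λ), and
`logsumreg benchmark` runs the full simulation grid and writes the
three summary tables (mean selected, mean selected within the preset
support, accuracy).

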