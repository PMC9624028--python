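# mlago

Machine-learning-aided constrained global optimization for Michaelis
constant (K_m) estimation in kinetic models.

## The problem

Kinetic models of biochemical networks are ODE systems
dx/dt = f(t, x, p) whose parameters — above all Michaelis constants —
are mostly unmeasured. Fitting them by global optimization alone
(minimize the badness-of-fit to time-course data) is expensive, often
lands on biologically unreasonable values, and is non-unique: many
parameter vectors fit the data equally well.

`mlago` attacks all three problems by combining two components:

1. **A K_m predictor** trained on curated (EC number, KEGG compound,
   organism) → K_m tables. Features are a hierarchical one-hot
   encoding: four one-hot blocks for the EC prefixes (class, subclass,
   sub-subclass, full code) plus one-hot compound and organism blocks,
   so related enzymes share feature bits. Learners: k-nearest
   neighbors, elastic net, random forest, gradient boosting.

2. **A constrained estimator** that treats the predictions q^ML (log10
   scale) as reference values:

       minimize   RMSE(q, q^ML)
       subject to BOF(p) ≤ AE,     p^L ≤ p ≤ p^U

   where BOF is the RMS relative error between simulated and measured
   concentrations, AE = 0.02 the allowable error, and the default box is
   10⁻⁵–10³ mM. The search engine is a real-coded genetic algorithm
   (ensemble crossover with just-generation-gap replacement, stochastic
   ranking for the constraint) operating in log10 coordinates.

The constraint guarantees a good model fit; minimizing the deviation
from references acts as regularization that pins a unique, plausible
solution. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from mlago import (
    ToyPathwaySpec, make_toy_pathway, generate_quasi_data,
    MlagoProblem, mlago_estimate, conventional_estimate, rmse,
)

# a 5-reaction Michaelis-Menten chain with known true K_m's,
# observed only through its boundary species (a non-identifiable setting)
model, p_true = make_toy_pathway(ToyPathwaySpec(n_reactions=5, seed=1))
data = generate_quasi_data(model, p_true, np.linspace(0.5, 10, 10),
                           molecules=["S0", "S5"])

q_true = np.log10(p_true[model.parameter_index(model.km_names)])
reference = q_true + 0.5   # biased references, mimicking imperfect predictions

res = mlago_estimate(MlagoProblem(
    model=model, data=data, searched_names=model.km_names,
    reference=reference, p_fixed=p_true.copy(), budget=8000, seed=100))
conv = conventional_estimate(model, data, model.km_names, p_true.copy(),
                             budget=8000, seed=100, reference=reference, ae=0.02)

print(f"constrained:  BOF={res.best_bof:.4f} feasible={res.feasible} "
      f"RMSE_to_truth={rmse(np.log10(res.best_p), q_true):.3f}")
print(f"conventional: BOF={conv.best_bof:.4f} feasible={conv.feasible} "
      f"RMSE_to_truth={rmse(np.log10(conv.best_p), q_true):.3f}")
```

Output:

```
constrained:  BOF=0.0198 feasible=True RMSE_to_truth=0.138
conventional: BOF=0.0227 feasible=False RMSE_to_truth=2.503
```

Within the same 8,000-simulation budget the constrained run found a
solution (BOF ≤ 0.02, i.e. within ~2% RMS relative error of the data)
whose K_m's sit ~0.14 log10 from the truth even though its references
were 0.5 log10 off. The unconstrained fit did not quite reach the same
fit quality in budget, and its K_m's wandered ~2.5 orders of magnitude
from the truth — a textbook non-identifiability symptom. Across
repeated seeds the constrained estimates are also nearly identical
(per-parameter SD ~0.02 log10 vs ~1.5 for the unconstrained mode; see
the acceptance output below).

## Command line

```
mlago curate measurements.tsv -o curated.tsv        # dedup by geometric mean
mlago train -c train.yaml -o model/                 # CV + fit a predictor
mlago predict -m model/ queries.tsv -o pred.tsv     # K_m in mM per query triple
mlago estimate -c problem.yaml -o run/              # constrained or conventional
mlago benchmark -c problem.yaml -n 10 -o bench/     # repeated-trial comparison
mlago make-fixtures -o fixtures/                    # desk-scale demo inputs
```

Every run writes a JSON manifest (config snapshot, seeds, input digests)
sufficient to reproduce it bit for bit.

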