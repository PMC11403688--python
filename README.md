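# gliomanet

Diagnostic gene networks and prognostic gene signatures for glioma from
transcriptomic data, under two WHO CNS classification schemes.

Adult diffuse gliomas are typed as astrocytoma, oligodendroglioma or
glioblastoma (GBM). The 2016 WHO criteria lean on histology; the 2021
criteria are driven by molecular markers (IDH mutation status and 1p/19q
codeletion), so a fraction of patients changes type between the two
schemes. `gliomanet` implements a two-step analysis that asks what this
reclassification does to (i) the gene networks that characterize each
glioma type and (ii) survival-based patient stratification:

1. **Network step.** Per glioma type, expression is gaussianized by the
   nonparanormal (rank-based Gaussian copula) transform, filtered to
   normally distributed genes by the Jarque–Bera test, and a sparse
   Gaussian graphical model is estimated by the graphical lasso

   maxΘ { log det Θ − tr(SΘ) − ρ‖Θ‖₁ },

   where S is the empirical covariance and Θ the precision matrix; a zero
   entry θᵢⱼ means genes i and j are conditionally independent. At a strong
   penalty most genes become unconnected, yielding a network-based variable
   selection. Connected genes are ranked by a *weight* measure
   mʷᵢ = Σⱼ≠ᵢ|θᵢⱼ| and a *count* measure (number of partners), both rescaled
   uniformly to [0, 100]; genes above percentile t = 60 on either scale are
   *hubs*.

2. **Survival step.** Over all glioma samples, a lasso-penalized Cox
   proportional-hazards model maximizes the partial log-likelihood
   Σᵢ δᵢ[xᵢβ − log Σⱼ:Yⱼ≥Yᵢ exp(xⱼβ)] − λ‖β‖₁ on three nested feature sets
   (case 1: all selected genes; case 2: genes exclusive to one type;
   case 3: hub genes). The active-set size is capped by the
   10-events-per-variable rule, pmax = ⌈events/10⌉, choosing the smallest λ
   whose model respects the cap. Each patient's prognostic index
   PI = xβ̂ is thresholded at the local minimum of a kernel density
   estimate between the two main PI modes (median if unimodal), and the
   resulting high-/low-risk groups are compared by Kaplan–Meier curves and
   the log-rank test (α = 0.05).

A seed-reproducible synthetic-data generator emulates the cohort structure
the analysis assumes: per-type block-sparse precision matrices, partly
non-Gaussian marginals, two partially discordant label schemes driven by
molecular flags, and right-censored exponential proportional-hazards
survival with a sparse true coefficient vector — with full ground truth for
recovery testing.

Intended users: computational biologists studying network-based biomarker
selection, and methodologists who want a tested, self-contained
implementation of glasso + penalized-Cox pipelines with known ground truth.

## Worked example

```python
import numpy as np
from gliomanet import simulate as sim, preprocess as pre, network as net, survival as surv

cfg = sim.SimulationConfig(n_per_type=150, p=120, seed=0)
ds = sim.generate_dataset(cfg)
X, report = pre.preprocess(ds.expression, alpha=0.05)

types = ds.clinical.set_index("sample_id")["type_2021"]
gbm = X.loc[types[types == "GBM"].index]
est = net.glasso_fit(net.empirical_covariance(gbm), rho=0.25)
selected = net.select_connected(est)
hubs = net.identify_hubs(net.hub_scores(est), t=60)

clin = ds.clinical.set_index("sample_id").loc[X.index]
data = surv.SurvivalData(clin["os_time"].to_numpy(), clin["os_event"].to_numpy(),
                         X[sorted(selected)])
model = surv.select_model(surv.cox_lasso_path(data), surv.compute_pmax(data.n_events))
pi = surv.prognostic_index(X[sorted(selected)], model)
strat = surv.stratify(pi, surv.kde_threshold(pi))
lr = surv.logrank_test(data, strat.group)
```

Output (seed 0):

```
genes kept after nonparanormal + Jarque-Bera filter: 120/120
GBM network: 40 connected genes, 23 hubs
events=303, pmax=31, active genes=31
HR=225, LR=225, log-rank p=1.99e-25
```

Reading: the filter keeps all 120 genes (the generator's monotone
distortions are undone by the nonparanormal transform); the GBM network
connects 40 genes (the truly co-regulated blocks plus a few
noise edges at this sample size), of which 23 clear the hub threshold;
with 303 death events the EPV rule allows 31 genes in the Cox model; the
KDE-threshold split separates survival between risk groups at p ≈ 2×10⁻²⁵.

The same workflow, for both schemes and all three cases with all artifacts
(networks as GraphML/edge lists, stratification tables, KM curves, summary
JSON) written to disk:

```sh
gliomanet run --seed 5 --outdir run5 --rho 0.25
gliomanet report run5 --plot
```

Subcommands `simulate`, `preprocess`, `network`, `survival` expose the
individual stages on TSV inputs; `--help` lists options.

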