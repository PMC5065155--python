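# dsbrepair

Stochastic modelling and hierarchical Bayesian inference of DNA
double-strand-break (DSB) repair kinetics.

## The problem

When cells are exposed to ionising radiation, double-strand breaks are
removed by several competing repair programmes with very different speeds:
fast non-homologous end joining (NHEJ, initiated by Ku/DNA-PKcs), slow
single-strand annealing (SSA, Rad52-dependent) and an intermediate
alternative end-joining route (A-EJ, PARP-1-associated).  Pulsed-field gel
electrophoresis (PFGE) assays measure the remaining damage over time as a
dose equivalent in Gray (1 DSB = 0.0286 Gy), and genetic knockouts switch
individual programmes off.  This package is for researchers who want to
turn a panel of such repair curves — wild type plus knockouts — into
statements about how many repair processes are active, how fast each one
is, and how many breaks each one handles.

## The model

Each channel *i* ∈ {fast, slow, aej} is a two-step mechanism acting on free
breaks *x* with a conserved pool of recruitment protein (*E_i* + *y_i* =
*C_i*):

    x + E_i  --K_i-->  y_i            (recruitment)
    y_i      --K'_i--> ∅ + E_i        (ligation)

simulated exactly with the Gillespie algorithm.  A knockout either removes
a channel or leaves it *binding-only* (the recruitment protein still binds,
downstream repair is dead).  Rates are tied together across datasets by a
hierarchical lognormal model: log *K* ~ N(μ_assigned, σ²), with μ₁…μ₃ the
population means of the fast/slow/intermediate log-rates, μ₄ governing
binding-only channels, and μ_i ~ U(α, β) a priori.  The hyperparameter
posterior π(γ | D₁…D₈) is sampled with ABC sequential Monte Carlo
(likelihood-free; only the hyperparameters are perturbed between
generations, per-dataset rates are redrawn from the hierarchy).  Nested
one/two/three-process variants are compared with information criteria on a
surrogate likelihood, and the fitted ensemble drives posterior-predictive
bands, per-mechanism repair tallies (Ñ_i = ∫K_i x E_i dt), half-maximum
repair times and pathway-activity timelines.

## A worked example

```sh
python examples/01_simulate_repair_curves.py
```

prints, for the wild-type configuration (20 Gy → 699 breaks) at the
package's reference median rates:

```
D1 (wild type MEF), dose 20 Gy
  t (h) :   0.00    0.25    0.50    1.00    2.00    4.00    8.00   12.00   24.00
  Gy    :  19.99   17.19   12.36    5.95    1.86    0.89    0.23    0.17    0.03
  fraction repaired by 2 h: 90.7%
```

The curve collapses within two hours because fast NHEJ out-competes the
other channels, while the Ku-deficient configuration (D5, 80 Gy) printed
below it decays over tens of hours — only the slow and intermediate
channels remain.  The other examples walk through hierarchical sampling
(`02`), a reduced-scale ABC SMC fit with parameter recovery (`03`), model
selection among one/two/three-process variants (`04`) and the posterior
analyses (`05`).

A thin CLI mirrors the pipeline stages
(`dsbrepair generate | fit | select-model | analyze | simulate`), each
writing tidy CSVs plus a JSON run manifest.

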