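# balnet

Compressive-sensing inference of sparse recurrent connectivity from the
dynamics of balanced excitatory/inhibitory networks of binary neurons.

## The problem

Recovering the wiring `R` of a neuronal network from recorded activity is
underdetermined in practice: an `N`-neuron network has `N²` potential
connections, far more than the measurements one can afford.  Two facts make
recovery feasible for cortical-like circuits: connectivity is **sparse**
(each neuron receives `K ≪ N` inputs per population), and networks operate
in a **balanced regime** where strong excitation and inhibition cancel
dynamically, giving the time-averaged dynamics a linear input–output
structure.

`balnet` implements the full in-silico pipeline for networks of binary
threshold neurons with asynchronous Poisson updates.  Time-averaging the
dynamics under a static random drive `p` gives the exact linear mapping

    mu_bar = R x_bar + F p,

where `x_bar` and `mu_bar` are the time-averaged states and total inputs.
Driving the network with `r` independent uniform random input vectors and
stacking the averages columnwise (`X`, `U`, `P`) turns each row of `R` into
an underdetermined linear system

    R_i X = U_i − (F P)_i ,

solved by L1 minimization (basis pursuit / lasso / BPDN / OMP), with no
constraint on connection signs — excitatory vs inhibitory identity is
*recovered*, not assumed.  Quality is measured by the relative Frobenius
error `ε = ||R − R_recon||_F / ||R||_F`, alongside support/sign metrics and
dynamical-regime diagnostics (E/I input-ratio statistics, quiescent and
saturated fractions).

Intended users: computational neuroscientists and applied mathematicians
studying network inference, balanced-state dynamics, or compressive sensing
on structured dynamical data.

## Worked example

```python
import numpy as np
from balnet import (NetworkParams, generate_connectivity,
                    generate_input_ensemble, run_ensemble, reconstruct,
                    SolverConfig, relative_error, check_balance_condition)

params = NetworkParams(N_E=320, N_I=80, K=10)   # balanced defaults otherwise
print(check_balance_condition(params))
# BalanceReport(lhs=1.2, mid=1.1111111111111112, satisfied=True)

network  = generate_connectivity(params, seed=0)
ensemble = generate_input_ensemble(params, r=300, seed=0)   # r < N: compressive
response = run_ensemble(network, ensemble, t_obs=2500.0, t_burn=500.0, seed=0)
result   = reconstruct(response, ensemble, network.f, SolverConfig())
print(f"relative error = {relative_error(network.R, result.R_recon):.3f}")
# relative error = 0.075
```

400 neurons have `160,000` potential connections; `300` trials supply
`300` measurements per row, yet the row-wise L1 solution recovers the
matrix to ~8% relative Frobenius error because each row has only
`2K = 20` nonzero entries in expectation.

The same pipeline from a shell:

```bash
balnet run --ne 320 --ni 80 --k 10 --trials 300 --seed 0 --out out/
balnet sweep --kind alpha_sweep --ne 320 --ni 80 --k 10 --trials 300 --out sweeps/
```

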