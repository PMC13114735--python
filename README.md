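# turingnet

Turing-pattern analysis of rumor propagation on complex networks: a
simulator and linear-stability toolkit for an SIR-type reaction–diffusion
model in which each compartment diffuses over its own network layer.

## The model

Online rumors spread by repeated exposure: a susceptible user adopts a
rumor only after multiple contacts with spreaders, which makes the
incidence quadratic in spreader density (social reinforcement).  With
logistic turnover of the susceptible pool, the local kinetics on each
network node *i* are

    dS_i/dt = d1 (A S)_i + r S_i (1 − S_i/K) − β S_i I_i² − μ1 S_i
    dI_i/dt = d2 (B I)_i + β S_i I_i² − (μ2 + α) I_i
    dR_i/dt = d3 (C R)_i + α I_i − μ3 R_i

where A, B, C are graph Laplacians (sign convention: adjacency minus
degree diagonal, so all eigenvalues ≤ 0) of three diffusion layers.  Each
edge of the underlying contact network carries a permission label — a
non-empty subset of {S, I, R} naming the compartments allowed to flow
across it — and decomposing by label yields the three layers.  When every
edge permits everything, A = B = C and the network is *homogeneous*.

Eliminating S and R from the steady state leaves a depressed cubic in I,

    f(I) = Kβ² I³ + Kβ(μ1 − r) I + r(μ2 + α),

with zero or two positive roots (branches "lower"/"upper").  Linearizing
about a branch gives, per Laplacian eigenvalue η on homogeneous networks,
the dispersion quadratic λ² + u(η)λ + v(η); the constant term v is negative
exactly on an interval (η1*, η2*) of negative eigenvalues, and a *Turing
instability* — a stable homogeneous state that breaks symmetry into a
stationary spatial pattern — requires a network eigenvalue strictly inside
that interval.  On heterogeneous networks, where the three Laplacians
cannot be co-diagonalized, the package evaluates necessary conditions
(H2/H3) built from a norm bound φ on the spectral radius of the full
3N×3N Jacobian, plus graph-Fourier diagnostics and a dense-Jacobian
eigenvalue oracle.

A calibration stage fits the aggregate model (plus cumulative adoption
N(t), dN/dt = βSI²) to a participation time series by greedy random-walk
least squares, with a synthetic-series generator, RMSE/MAPE scoring and
recovery-rate intervention experiments.

## Worked example

```python
import turingnet as tn

params = tn.PRESET_PATTERN          # r=2.6, K=0.5, β=0.8, μ1=0.4, μ2=0.1,
                                    # μ3=0.3, α=0.1, d1=10, d2=0.1, d3=0.1
for eq in tn.solve_equilibria(params):
    rep = tn.h1_check(eq, params)
    print(f"{eq.branch:>5} branch: S*={eq.S_star:.4f} I*={eq.I_star:.4f} "
          f"R*={eq.R_star:.4f}  H1={rep.holds}")

upper = tn.solve_equilibria(params)[1]
interval = tn.turing_interval(upper, params)
print(f"Turing interval: ({interval.eta1_star:.4f}, {interval.eta2_star:.4f})")

net = tn.build_lattice(16, 16, degree=4, boundary="periodic")
rep = tn.homogeneous_turing_report(net, upper, params)
print(f"16x16 torus: Turing-capable={rep.turing_capable}, "
      f"unstable modes={len(rep.unstable_modes)}")

init = tn.perturbed_equilibrium_init(upper, net.n_nodes, amplitude=0.01, seed=7)
traj = tn.integrate(net, params, init, dt=0.02, t_end=2000, stride=10**9)
stats = tn.pattern_stats(traj.final.I)
print(f"after t=2000: sd(I)={stats.sd:.3f} (initial {init.I.std():.4f}), "
      f"range [{stats.min:.3f}, {stats.max:.3f}]")
```

prints

```
lower branch: S*=0.3398 I*=0.7357 R*=0.2452  H1=False
upper branch: S*=0.2149 I*=1.1632 R*=0.3877  H1=True
Turing interval: (-1.7699, -0.1183)
16x16 torus: Turing-capable=True, unstable modes=36
after t=2000: sd(I)=1.021 (initial 0.0065), range [0.171, 3.385]
```

Only the upper equilibrium branch is stable to homogeneous perturbations
(H1).  Because the susceptible layer diffuses 100× faster than the
spreader layer, 36 lattice modes fall inside the unstable interval; a 1%
random perturbation of the equilibrium grows ~150-fold in standard
deviation and saturates into a stationary spotted pattern in which nodes
hold spreader densities from 0.17 to 3.4 around the uniform value 1.16.

The same pipeline is scriptable from the shell:

```
turingnet net --kind ql --rows 32 --cols 32 --out torus.tsv
turingnet stability --network torus.tsv --params params.yaml --branch upper
turingnet simulate --network torus.tsv --params params.yaml --t-end 2000 --out state.csv
turingnet spectra --network torus.tsv --state state.csv --out scatter.csv
```

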