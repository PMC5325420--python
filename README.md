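# crosstalksim

Kinetic simulation of crosstalk-linked signaling modules, with in-silico
screens of targeted-drug efficacy, crosstalk-mediated drug resistance and
drug-combination synergy.

## The problem

Parallel signaling cascades (think EGFR→ERK alongside HGFR→AKT) rarely run
independently: crosstalk links let one pathway activate or inhibit the
other, and those links can blunt — or sharpen — the effect of a drug that
targets a single node. `crosstalksim` models the minimal setting in which
this happens: two three-node cascades, `G1 → A → B → O` and
`G2 → C → D → O`, converging on one output `O`, plus zero, one or two
crosstalk edges. Nine module topologies (M0–M8) cover the common one- and
two-link crosstalk motifs; M0 has no crosstalk and serves as the baseline.
The package is for systems/computational biologists who want a small,
fully controlled sandbox for asking which network architectures produce
drug resistance and which target pairs rescue it.

## The model

Each species is an activation fraction `X_i ∈ [0, 1]` obeying

    dX_i/dt = Σ_j act(j→i) + Σ_j inh(j→i) − d_i·X_i + f_i(t)

with saturating edge kinetics

    act(j→i) = V_ji · (1 − X_i) / (g_i·K_ji + (1 − X_i)) · X_j     (V_ji > 0)
    inh(j→i) = V_ji ·      X_i  / (g_i·K_ji +      X_i)  · X_j     (V_ji < 0)

and receptor inputs `f_1 = V_A·G1(t)/(g_1·K_A + G1(t))`,
`f_3 = V_C·G2(t)/(g_3·K_C + G2(t))`. A drug targeting species *i* is a
competitive inhibitor of its activation: it inflates every Michaelis
constant of routes into *i* by `g_i = 1 + dose/K_D`. Standard parameters:
`V = +0.4` (activation), `−1` (inhibition), `K = 0.8`, `d = 0.2`,
`V_A = V_C = 0.2`, `K_A = K_C = 0.5`, `K_D = 0.1`. Integration is classical
fixed-step RK4 (`h = 0.01`, horizon `T = 100`) from `X(0) = 0`.

Two scalar indices summarize a run:

* **Relative drug efficacy** — with `IO = ∫₀ᵀ O(t) dt`,
  `RDE(i) = (1 − IO_drug(i)/IO_no_drug(i)) − (1 − IO_drug(0)/IO_no_drug(0))`.
  `RDE < 0` means the module's crosstalk blunts the drug relative to the
  crosstalk-free baseline: drug resistance.
* **Bliss combination index** — with `R` the fractional reduction of IO,
  `CI = R₁₂ − (R₁ + R₂ − R₁·R₂)`; `CI > 0.05` synergy, `CI < −0.05`
  antagonism, else additivity.

## Worked example

```python
from crosstalksim import *

params = default_parameters()
stimuli = stimulus_library()["S0"]          # unit pulse on t ∈ [0, 30)
drug = DrugRegimen.single("B", dose=1.0)    # B-targeting drug from t = 0

for module_id in (0, 1, 2):
    topo = build_module(module_id)
    io_off = integrated_output(simulate(topo, params, stimuli))
    io_on = integrated_output(simulate(topo, params, stimuli, drug))
    print(f"module {module_id}: IO untreated = {io_off:6.2f}, "
          f"IO drug = {io_on:6.2f}, reduction = {1 - io_on/io_off:.3f}")
```

prints

```
module 0: IO untreated =  24.37, IO drug =  17.59, reduction = 0.278
module 1: IO untreated =  27.94, IO drug =  22.59, reduction = 0.191
module 2: IO untreated =  19.15, IO drug =   9.68, reduction = 0.495
```

Module 1 (A activates D) leaks signal around the drugged node B, so the
drug removes only 19% of its output versus 28% in the crosstalk-free
module 0 — `RDE(1) = 0.191 − 0.278 = −0.087`, i.e. resistance. Module 2
(A inhibits D) does the opposite: the drug also starves the inhibitory
link's source, output collapses by 49%, and `RDE(2) = +0.217`.

The same protocols are available from the shell:

```sh
crosstalksim screen-single --out results/           # RDE of all 9 modules
crosstalksim screen-combo  --out results/ --plot    # Bliss CI heatmap
crosstalksim scan-strength --out results/           # RDE vs crosstalk scale
crosstalksim scan-stimulus --out results/           # robustness to input shape
```

Each command writes a tidy CSV plus a JSON manifest (config echo, package
version, hashes) so a result directory is self-describing.

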