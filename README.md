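# pytagsim

Mass-action modeling and trace quantification for **pYtag-style RTK
translocation biosensors**.

A pYtag biosensor labels a receptor tyrosine kinase (RTK) with a tyrosine
activation motif; a fluorescent tandem-SH2 reporter binds the phosphorylated
motif when the receptor is activated, depleting the reporter from the
cytosol.  The fraction of reporter cleared from the cytosol is therefore a
live, quantitative readout of receptor activity.  This package is for
quantitative cell biologists who want to (i) simulate how that readout
responds to ligand dose, ligand identity, receptor mutations and biosensor
expression levels, and (ii) quantify measured (or synthetic) per-cell
intensity timeseries the same way the imaging analyses do.

## The model

EGFR-class receptor activation is described by mass-action kinetics over
three per-receptor binary states — ligand-bound, dimerized, reporter-bound —
giving 16 species: free ligand *N₁* (clamped; ligand is in vast excess),
free reporter *N₂*, four monomer states and ten dimer states.  The rate
constants are

| constant | process | default |
|---|---|---|
| k₁ | ligand association | 10⁷ M⁻¹s⁻¹ |
| k₇ | ligand dissociation (scaled by **β**) | 2×10⁻² s⁻¹ |
| k₅ | receptor dimerization + autophosphorylation (lumped) | 10⁴ M⁻¹s⁻¹ |
| k₆ | ligand-free (inactive) dimer dissociation | 5×10⁻³ s⁻¹ |
| k₃ | ligand-bound (active) dimer dissociation (scaled by **γ**) | 10⁻⁴ s⁻¹ |
| k₂ | reporter association to an active dimer tail | 10⁷ M⁻¹s⁻¹ |
| k₄ | reporter dissociation | 10⁻¹ s⁻¹ |

with receptor total *N<sub>E,o</sub>* from 250,000 receptors in a 10 µm
sphere (≈ 9.91×10⁻⁸ M) and reporter at a 1:1 molar ratio.  A ligand's
identity is two fold-changes relative to EGF: **β** multiplies k₇ (binding
affinity) and **γ** multiplies k₃ (dimerization affinity of ligand-bound
receptors); β = γ = 1 is EGF.

Before stimulation receptor exists only as monomer *N₃* and pre-formed
inactive dimer *N₅*, partitioned by

    N_E,o = N₃,ₒ + 2 N₅,ₒ,    k₅ N₃,ₒ² = k₆ N₅,ₒ

whose closed-form root (evaluated in a cancellation-free form) is the exact
initial condition of every simulation.  The model-side observable is the
cytosolic clearance `100·(Z_total − Z_free)/Z_total` (%), and the
measurement-side quantification is the baseline-normalized intensity drop

    activity(t) = −100 · (I_cyt(t) / I_cyt,o − 1)

so both live on the same scale.

## Worked example

```python
import pytagsim as pt

params = pt.ModelParameters()
traj = pt.simulate_timecourse(params, pt.LigandSpec(name="EGF", dose_ng_ml=20.0))
print(round(traj.clearance_at(60), 1), round(traj.clearance_at(1800), 1))
print(pt.classify_kinetics(traj).label)
```

prints

```
21.6 41.7
biphasic-rising
```

— at 20 ng/mL EGF, 21.6 % of the reporter has left the cytosol after one
minute (ligand loading onto the pre-formed dimer pool) and 41.7 % after 30
minutes (slow dimerization of liganded monomers); the trace is classified
as biphasic-rising, the high-dose EGF signature.  Weakening the
dimerization of ligand-bound receptors flips the shape:

```python
tr = pt.simulate_timecourse(params, pt.LigandSpec(gamma=100.0, dose_ng_ml=20.0))
print(pt.classify_kinetics(tr).label)   # -> peak-plateau
```

The `examples/` directory walks through each capability: single
timecourses, the (β, γ) dose panels, the GBM-mutant prediction, the
expression-ratio sweep, quantification of a noisy synthetic population
(artifact repair, hierarchical replicate aggregation), and recovery of
(β, γ) from noisy traces by multi-start least squares.

## Layout

- `src/pytagsim/network.py` — species catalogue and declarative reaction list
- `src/pytagsim/parameters.py` — rate constants, ligand specs, unit conversions, config I/O
- `src/pytagsim/kinetics.py` — compiled mass-action RHS and integrators
- `src/pytagsim/equilibrium.py` — analytic pre-stimulus state
- `src/pytagsim/simulate.py` — timecourses, dose panels, regimes, scenarios
- `src/pytagsim/quantify.py` — intensity-table quantification
- `src/pytagsim/synthetic.py` — seeded synthetic-data generator with ground truth
- `src/pytagsim/fitting.py` — (β, γ) estimation and recovery reports
- `docs/methods.md` — modeling and quantification methods in detail
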