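# npkinetics

Kinetics of L1-ORF1p nucleoprotein assembly on single-stranded DNA
under force.

ORF1p, the trimeric nucleic-acid binding protein of the LINE-1
retrotransposon, coats long single strands and switches between two
bound conformations: a *compact* state (one trimer fully engaging
~50 nt, maximal shortening of the strand) and a *de-compact* state
(two trimers crowding one footprint with partial engagement, less
shortening, faster dissociation).  In a force-clamp optical-tweezers
experiment this shows up as a biphasic extension record: rapid
compaction, partial re-elongation as excess protein invades, then —
after washing out free protein — fast re-compaction and slow final
dissociation.  Slow oligomerization of neighbouring trimers protects
the bound protein ~10-fold against dissociation.

`npkinetics` is for single-molecule biophysicists who want a tested,
reproducible implementation of this system: a continuous-time
(Gillespie) lattice simulator that generates realistic force-clamp
traces for every experiment family (concentration series, force
series, incubation-time series, oligomerization-deficient and
monomeric variants), a matching mean-field ODE, and the full analysis
chain — monotonic-phase segmentation, exponential phase fits,
occupancy isotherm, saturating concentration dependence
k(c) = a·c·b/(a·c + b), Bell force law k(F) = k₀·e^(F·Δx†/k_BT), and
the oligomerization time course k(t) = k_∞ + (k₀ − k_∞)e^(−t/τ) — so
that every rate constant of the scheme is recoverable from synthetic
ensembles.  The model and its calibration are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate ten replicate force-clamp records (8.1 knt ssDNA at 30 pN,
100 s in 30 nM trimer, then 400 s of protein-free buffer) and extract
the four phases:

```python
from npkinetics import (LatticeConfig, Protocol, Segment,
                        reference_params, simulate_trace,
                        summarize_condition)

params = reference_params()          # calibrated reference rate set
config = LatticeConfig()             # 8100 nt = 162 trimer sites
schedule = (Segment(100.0, 30.0),    # 100 s in 30 nM trimer
            Segment(400.0, 0.0))     # washout
protocol = Protocol(force=30.0, schedule=schedule, seed=7)
traces = [simulate_trace(config, params,
                         Protocol(force=30.0, schedule=schedule, seed=7 + i))
          for i in range(10)]
s = summarize_condition(traces, protocol)
print(f"initial compaction:    dx = {s.dx_plus_i:.3f} nm/nt, k = {s.k_plus_i:.2f} 1/s")
print(f"partial elongation:    dx = {s.dx_plus_f:.3f} nm/nt, k = {s.k_plus_f:.2f} 1/s")
print(f"washout re-compaction: dx = {s.dx_minus_i:.3f} nm/nt, k = {s.k_minus_i:.3f} 1/s")
print(f"final dissociation:    k = {s.k_minus_f:.4f} 1/s")
```

prints

```
initial compaction:    dx = 0.200 nm/nt, k = 0.59 1/s
partial elongation:    dx = 0.116 nm/nt, k = 0.10 1/s
washout re-compaction: dx = 0.219 nm/nt, k = 0.071 1/s
final dissociation:    k = 0.0070 1/s
```

Amplitudes are extension reductions from the bare strand per
nucleotide; the partial elongation shows the crowding transition into
the de-compact state, and the washout re-compaction rate (0.071 1/s)
sits between the unprotected (0.11) and oligomer-protected (0.01)
limits because flags have accumulated for 100 s ≈ τ_oligo.  Per-phase
exponential rates are descriptive; parameter-level estimates use the
joint and trajectory fits described in the methods note.  Recovering a
printed constant end to end is one call:

```python
from npkinetics import reproduce_target
report = reproduce_target("dissociation_rate_ratio", seed=2)
print(report.measured)   # ~16.5-fold, expected ~15-fold
```

The same pipelines are available from the shell:

```sh
npkinetics simulate --conc 30 --seed 7 --out trace.tsv
npkinetics analyze trace.tsv --out phases.json
npkinetics series binding_concentration --seed 1 --out series.json
npkinetics reproduce oligomerization_timescale --seed 1
```

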