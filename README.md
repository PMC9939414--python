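# coilflow

Pulsatile non-Newtonian blood flow in a coiled bilobed cerebral aneurysm:
a 2D immersed-geometry CFD pipeline for quantifying how endovascular coil
porosity and blood hematocrit reshape wall shear stress (WSS), the
oscillatory shear index (OSI), wall pressure and neck inflow.

## Who this is for

Researchers in computational hemodynamics who want a small, fully
deterministic, analytically benchmarked sandbox for aneurysm-coiling
physics: the jet through the aneurysm neck, the twin recirculating domes,
the porous damping of a coiled sac, and the rheological effect of the
red-cell fraction — without the cost and irreproducibility of a
patient-specific 3D pipeline.

## The model

Incompressible laminar Navier–Stokes on a staggered Cartesian grid, solved
with a projection scheme.  Blood viscosity follows a regularised Casson
law with hematocrit-dependent yield stress,

    mu = 0.1 ( sqrt(eta) + sqrt( tau_y (1 - e^{-m gdot}) / gdot ) )^2,
    tau_y = (0.625 H)^3,

(eta in poise, tau_y in dyn/cm², mu in Pa·s), so a higher hematocrit H
stiffens the fluid at low shear while the high-shear viscosity 0.1·eta
stays fixed.  The vessel wall is imposed by Brinkman volume penalization on
a level-set geometry (straight parent channel + two overlapping dome discs
joined through a neck), and the coil is a Darcy momentum sink
-(mu/K)·u over the packed sac, with Kozeny–Carman permeability
K = d_w² φ³ / (180 (1-φ)²).  The inlet carries a parametric cardiac
waveform with four detected phase markers (maximum acceleration, peak
systole, maximum deceleration, early diastole); three cycles are run and
the last one analysed.

Wall indices: signed WSS by wall-normal velocity probes,
TAWSS = cycle mean of |τ_w|, and OSI = ½(1 − |⟨τ_w⟩|/⟨|τ_w|⟩), plus
per-phase maxima, neck-plane average velocity and a wall-load export for
one-way structural coupling.  Full details and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from coilflow import (GeometryParams, RheologyParams, CoilModel,
                      build_geometry, coil_mask, synth_waveform, run_cycles)
from coilflow.indices import phase_metrics

geo = coil_mask(build_geometry(GeometryParams(grid_nx=128, grid_ny=64,
                                              dx=13e-3 / 64)), 1.0)
wf = synth_waveform()                       # 0.8 s cycle, 0.15..0.55 m/s
rheo = RheologyParams(H=0.35)               # female-typical hematocrit
coil = CoilModel(porosity=0.79)
res = run_cycles(geo, wf, rheo, coil=coil)
report = phase_metrics(res.final_cycle_series, res.snapshots, wf.phases,
                       geo, rheo, label="hct35_phi079", porosity=0.79)
print(round(report.max_wss["peak_systole"], 2), "Pa peak-systolic max WSS")
print(round(report.neck_avg_velocity["max_accel"], 3), "m/s neck velocity")
```

prints (at this reduced 64×128 resolution)

```
5.38 Pa peak-systolic max WSS
0.137 m/s neck velocity
```

— the largest wall shear sits at the aneurysm neck at peak systole, and
the neck-plane velocity shows how much flow still enters the coiled sac.

The full study is driven by the numbered scripts:

```sh
python analysis/01_geometry_and_waveform.py   # build + export the inputs
python analysis/02_benchmarks.py              # analytic solver validation
python analysis/03_hct_porosity_study.py      # 6-condition HCT x porosity sweep
python analysis/04_grid_convergence.py        # neck-velocity grid study
```

each writing its tables under `results/`.  The same operations are exposed
as a CLI: `coilflow run`, `coilflow converge`,
`coilflow benchmark poiseuille|womersley|darcy|casson-channel|all`,
`coilflow config --defaults`.

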