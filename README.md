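# aortaflow

Inlet boundary-condition (BC) sensitivity analysis for thoracic-aorta
hemodynamics, built to run end-to-end on synthetic pulsatile tube flows.

## The problem

Image-based computational studies of aortic flow must prescribe a velocity
profile at the ascending-aorta inlet. In patients with an abnormal aortic
valve (stenosis, mechanical prosthesis), the inflow is an eccentric,
swirling jet whose secondary (in-plane) components can account for half of
the total velocity — yet most studies impose either a flat plug profile or
only the through-plane component measured by phase-contrast MRI (PC-MRI).
`aortaflow` quantifies what that simplification costs. It builds the three
standard inlet variants from (emulated) PC-MRI plane data,

* **FLAT** — spatially uniform normal velocity `Q(t)/A`,
* **TP** — the measured through-plane component only, `v·n̂ n̂`,
* **3D** — all three measured components (the benchmark),

all rescaled to carry the identical flow waveform `Q(t)`, and compares the
hemodynamic descriptors each produces:

* wall shear stress `τ_w = [μ(∇v + ∇vᵀ)n̂]_tangential`, its time average
  **TAWSS** = (1/T)∫|τ_w|dt, and the oscillatory shear index
  **OSI** = ½(1 − |∫τ_w dt| / ∫|τ_w|dt) ∈ [0, ½];
* helicity density **Hk** = v·(∇×v) and local normalized helicity
  **LNH** = Hk/(|v||∇×v|) ∈ [−1, 1];
* the Lagrangian **helicity flow index (HFI)** ∈ [0, 1]: mean |LNH| along
  4th-order Runge–Kutta particle traces released at four systolic instants
  T1–T4, averaged over particles and release times;
* a three-element **Windkessel** outlet, `P + R_d C dP/dt =
  (R_p + R_d)Q + R_p R_d C dQ/dt`, integrated to its periodic solution.

Because no patient data ship with the package, a first-class synthetic-flow
module generates the study conditions: analytic laminar oracles
(Poiseuille, swirling Poiseuille, Womersley) for validation, and a
kinematic valve-jet surrogate — an eccentric Gaussian systolic jet with
solid-body swirl calibrated so secondary flow averages 51% of the total
inlet velocity (the severe-stenosis condition), imaged at 1.4 × 1.4 × 10 mm
voxels, 100 phases per cycle, VENC 10% above the expected peak, with
Gaussian noise and ±2·VENC aliasing.

## Worked example

```python
import aortaflow as af

cfg = af.StudyConfig(seed=1, n_phases=50, np_particles=100)
report = af.run_study(cfg)
pt = report.cells["wss_percent_diff"]["FLAT"]["TAWSS"]
print(pt["AAo"], pt["DAo"])
```

Running `python examples/05_full_study.py` prints (among more):

```
TAWSS percent difference vs 3D benchmark:
  FLAT: whole  -52.7%  AAo  -82.2%  AA  -37.9%  DAo  -10.9%
    TP: whole  -21.2%  AAo  -32.4%  AA  -16.0%  DAo   -4.9%
Windkessel outlet: 125/78 mmHg
```

Read: imposing a flat inlet profile underestimates time-averaged wall shear
stress by 82% in the ascending aorta of this synthetic stenotic scenario,
but only 11% in the descending aorta — the penalty for ignoring the inlet
jet shape decays downstream, while the through-plane-only profile is an
intermediate compromise. The Windkessel outlet settles at a physiological
125/78 mmHg. Each `examples/*.py` script demonstrates one capability
(inlet profiles and velocity decomposition, Windkessel, WSS/TAWSS/OSI,
helicity/HFI, full study) and prints what the numbers mean.

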