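# killfrac

Spatio-temporal modelling of chemotherapy transport and tumor cell kill
around a blood vessel, for researchers in mathematical oncology and
drug-delivery engineering who want to quantify how *sustained* drug release
(e.g. from nano-carriers lodged in the tumor vasculature) outperforms
conventional bolus dosing.

## The model

Drug at concentration σ diffuses from a vessel of radius r_b into the
surrounding tissue, is taken up by viable tumor cells (volume fraction φ),
and kills them in proportion to cumulative exposure:

    ∂σ/∂t = D ∇²σ − λ_u φ σ          (quasi-steady: solved at ∂σ/∂t ≈ 0)
    ∂φ/∂t = −λ_u λ_k φ ∫₀ᵗ σφ dτ

Scaling lengths by the diffusion penetration length L = √(D/(φ₀λ_u)) and
time by the apoptotic-cycle time T = (λ_k λ_u φ₀ σ₀)^(−1/2) leaves a
parameter-free system on the annulus between the vessel wall (r′ = r_b/L,
where σ′ = 1) and the edge of the vessel's influenced tissue volume
(r′ = r_b/(L√BVF), zero flux), so each simulation is fully determined by two
numbers: **r_b/L** and the blood volume fraction **BVF**. The headline
output is the kill fraction

    f_kill(t′) = 1 − 2∫ φ′ r′ dr′ / (R′² − (r_b/L)²),

the killed-to-initial tumor volume ratio in the annulus. A companion
closed-form tier covers nano-carriers releasing drug at constant mass flux F:
f_kill = Fλ_k t²/(2V_T0), equivalently Λ_k t/(2V_T0) in terms of the
measurable net volumetric death rate Λ_k, with the kill-time estimate
t_kill = 2V_T0 f/Λ_k. See `docs/methods.md` for the numerics and design
choices.

## Worked example

```python
from killfrac import (DimensionlessParams, run_kill_curve,
                      total_dose, net_death_rate, time_to_kill)

# clinically calibrated geometry: r_b = 15.83 um, L = 155.06 um -> r_b/L = 0.102
curve = run_kill_curve(DimensionlessParams(rb_over_L=0.102, BVF=0.01), t_end=4.0)
bolus = curve.at(1.0)
print(f"f_kill after 1 cycle (bolus reference): {bolus:.3f}")
print(f"f_kill after 4 cycles (sustained release): {curve.at(4.0):.3f}")
print(f"enhancement over bolus: {curve.at(4.0)/bolus:.2f}-fold")

# in-vivo arithmetic for a treated mouse cohort
print(f"total dose (6 mg/kg, 20 g mouse): {total_dose(6.0, 20.0):.1e} g")
lam_k = net_death_rate(70.0, 35.0)   # control vs treated growth, mm^3/day
print(f"net death rate: {lam_k:.0f} mm^3/day")
print(f"time to half-kill a 130 mm^3 tumor: {time_to_kill(0.5, lam_k, 130.0):.2f} days")
```

prints

```
f_kill after 1 cycle (bolus reference): 0.237
f_kill after 4 cycles (sustained release): 0.957
enhancement over bolus: 4.04-fold
total dose (6 mg/kg, 20 g mouse): 1.2e-04 g
net death rate: 35 mm^3/day
time to half-kill a 130 mm^3 tumor: 3.71 days
```

Reading: a bolus regimen kills about a quarter of the tissue in this
vessel's territory; a carrier sustaining the same wall concentration for
four apoptotic cycles kills nearly all of it — a ~4-fold enhancement. The
last three lines reproduce the dose and kill-time bookkeeping for a mouse
experiment: at a 35 mm³/day net death rate, half-killing a 130 mm³ tumor
takes ≈ 3.7 (~4) days.

## Command line

```sh
killfrac kill-curve --rb-over-l 0.102 --bvf 0.01 --t-end 10 --out out/
killfrac sweep --out sweep/              # 3x3 (r_b/L x BVF) grid + bolus-normalized twins
killfrac synth cohort --n 21 --seed 1 --out data/
killfrac calibrate --cohort data/cohort.csv --r-b 15.83 --out fit/
killfrac predict --hu 30 --fit fit/fit.json
killfrac synth mouse --seed 1 --out data/
killfrac mouse-analyze --in data/volumes.csv --out analysis/
```

Every run writes CSV/JSON outputs plus a `provenance.json` recording the
parameters, seed and package version.

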