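# Methods

This note documents the model, its numerical treatment, the synthetic-data
conditions, and the design choices that were genuinely open.

## The closed-loop 0D circulation

The circulation is the classic lumped-parameter closed loop with carotid
baroregulation of Ursino (Am J Physiol 274, 1998): eight vascular
compartments — systemic arteries; splanchnic and extrasplanchnic peripheral
and venous beds in parallel; pulmonary arteries, peripheral bed and veins —
plus four cardiac chambers. Every constant lives in the versioned file
`src/lvadest/data/ursino1998.yaml`; the code never hard-codes a value.

Per compartment *i* (units: mmHg, ml, s):

- mass: dV_i/dt = Q_in − Q_out
- momentum (large arteries only): L_i dQ_out/dt = P_in − P_out − R_i Q_out
- pressure–volume: V_i = C_i P_i + V_{i,0}

Atria are passive compliances with an outlet resistance and an ideal diode
valve. Ventricles follow the time-varying-elastance description: with
activation φ(t) = sin²(π t / T_sys) during systole (T_sys = T_sys,0 −
k_sys/T, zero in diastole), the isovolumic pressure is

    P_max = φ·E_max(t)·(V − V_u) + (1 − φ)·P_0·(e^{k_E·V} − 1),

outflow passes a diode in series with a flow-proportional viscous loss
R = k_R·P_max, and P_v = P_max − R·Q_out.

**Baroreflex.** The carotid afferent filters P_sa + τ_zp dP_sa/dt through a
first-order lag (τ_p) and maps it through a sigmoid to the firing rate
f_cs; static efferent characteristics give sympathetic (f_es, decreasing in
f_cs) and vagal (f_ev, increasing) activities. Each effector θ ∈
{E_max,lv, E_max,rv, R_sp, R_ep, V_u,sv, V_u,ev, T_sym} follows

    θ(t) = θ₀ + x(t),  τ dx/dt = σ(f_es(t − D)) − x,
    σ = G·ln(f_es − f_es,min + 1),

and the vagal heart-period branch uses σ = G·f_ev(t − D). The heart period
is T = T₀ + x_sym + x_vag; beats are triggered by a phase clock dξ/dt =
1/T(t), with the period and systolic duration frozen at each beat onset.

**Transcription caveats.** The constants are transcribed from the source
model; two structural points are this package's own choices and are flagged
here. (i) A single inertial branch cannot feed two distinct peripheral
pressure nodes, so the systemic R_sa/L_sa branch is implemented as two
parallel inertial branches with conductances proportioned to the basal
splanchnic/extrasplanchnic conductances (their parallel combination equals
R_sa, L_sa exactly). (ii) The extrasplanchnic resistance gain G_Rep is set
proportionally to G_Rsp by the resistance ratio. Basal closure was checked
against the source model's reported operating point (mean systemic pressure
~95–105 mmHg, heart rate ~70 min⁻¹, cardiac output ~5–5.8 l/min, LV
ejection fraction ~58% at the healthy parameter point).

## Heart-failure parameterization

Severity is controlled by four parameters sampled independently and
uniformly: E_max,lv ∈ [0.200, 2.95] mmHg/ml, E_max,lv,0 ∈ [0.200, 2.39]
mmHg/ml, G_Emax,lv ∈ [0.200, 0.475] mmHg/ml per unit ln-drive, k_E,lv ∈
[0.0110, 0.0140] ml⁻¹. The elastance effector uses E_max,lv,0 as its offset
and G_Emax,lv as its gain; its state is initialized so the run *starts* at
the operating elastance E_max,lv and relaxes toward the regulated value
with the effector's 8 s time constant. Because features are encoded over
the full 30 s record (below), the early low-frequency transient carries the
information that makes E_max,lv identifiable separately from E_max,lv,0 —
with a consistent initial state and zero gain the elastance is exactly
constant, which is the degenerate case the tests pin down.

## The pump

The LVAD is a pressure-controlled flow generator from LV apex to systemic
arteries: Q_pump = Φ(ω(t), ΔP) with ΔP = P_sa − P_lv, read from a tabulated
H–Q characteristic by bilinear interpolation (exact at nodes; ΔP clamped to
the table domain with a warning; speeds must cover the set-speed grid ±
the pulse amplitude). Cannulas are ideal (zero resistance) by default.

The shipped table (`data/hmiii_surrogate_curve.csv`) is **synthetic**: the
manufacturer's curves are not redistributable, so a centrifugal surrogate
Q = sqrt(max(A·(ω/1000)² − ΔP, 0)/C₂) with A = 3.8 mmHg, C₂ = 0.00444
mmHg/(ml/s)² is tabulated over 2000–8000 RPM × 0–150 mmHg. A and C₂ were
chosen once to match publicly known device features — zero-flow head
~95 mmHg at 5000 RPM scaling with speed², flows of roughly 2.5/4.5/7.4
l/min at 70 mmHg for 4000/5000/6000 RPM, and a pressure sensitivity of
~1.5 ml s⁻¹ mmHg⁻¹ at the operating point. Reverse (negative) flow is
clamped to zero. Any user table in the same CSV layout (l/min or ml/s,
declared in a header comment) can replace it.

**Artificial pulse.** Every 2 s the speed drops by 2000 RPM for 0.15 s and
then sits 2000 RPM *above* the set speed for 0.20 s before returning — the
stated rise of 4000 RPM is read as relative to the reduced level, the
reading supported by the sequential phrasing of the source description.
The cycle is anchored at t = 0 and is asynchronous with the heartbeat.
Consequences used as test oracles: modulated duty fraction 17.5%, mean
modulated speed ω_c + 50 RPM, and a strong 0.5 Hz line in the arterial
pressure spectrum.

## Numerics

The coupled system (25 states) is advanced by classical RK4 at a fixed step
(default ≤ 0.5 ms, chosen to divide the output grid exactly). Design
rationale: the ideal-diode valves make the right-hand side non-smooth,
which defeats the step-size control of adaptive stiff integrators, whereas
at 0.5 ms the fastest time constants (arterial inertances, ventricular
viscous losses) are resolved; pure efferent delays (0.2–5 s) become exact
ring-buffer lookups; and runs are bit-deterministic. Halving the step twice
changes the systemic pressure trace by < 1% of its standard deviation
(self-convergence test). The pump's implicit coupling (Q_pump depends on
P_lv which depends on total outflow) is resolved by one fixed-point pass —
the residual is second order in k_R·Q. Volume conservation is structural
(every flow appears once as inflow and once as outflow) and is enforced at
0.1% as a run-acceptance check; runs reaching a non-physical state raise
`SimulationFailure` and are resampled during data generation with logged
counts.

Initial volumes distribute the 5300 ml total as unstressed volumes plus
compliant filling at nominal pressures, the residual going to the venous
beds; effectors start at their basal targets (LV elastance at E_max,lv).
The first beats are transient, which is why T = 30 s is integrated and
summaries use only the final window.

## Fourier features

A record u(t_m), t_m = mT/N (T = 30 s, N = 2000), is encoded by real FFT
over its first N samples into trigonometric coefficients of the synthesis
formula u = a₀/2 + Σ_k [a_k cos ω_k t + b_k sin ω_k t], ω_k = 2πk/T.
Truncation keeps c = (a₀…a_{K−1}, b₁…b_{K−1}); at K = 50 the estimator
input is (c_SAP, c_PAP, ω_c) ∈ R¹⁹⁹ (the *set* speed, not the modulated
one). Coefficients cover the full record including the initial transient —
deliberately, see the identifiability argument above; a steady-state-window
encoding is available for sensitivity studies via the spec argument. At
full order (K = N/2 + 1, Nyquist term carrying its closure weight) encoding
inverts exactly on the grid, and truncation error is monotone in K
(Parseval); K = 50 reconstructs even the richest waveform (severe failure
at 4000 RPM, native ejection + artificial pulse) with RMS error < 5% of the
signal SD.

## Estimator

MLP with ReLU hidden layers and sigmoid outputs; labels are min-max scaled
to (0,1) using the configured sampling ranges (the generator's ground
truth, not empirical extremes); inputs are z-scored with training-set
statistics stored in the model artifact. Training minimizes MSE with Adam
(lr 0.001, batch 32), epoch budget 200 with early stopping (patience 20)
and best-validation-epoch checkpointing. The split holds out 5% for test,
then 80/20 of the remainder for train/validation, stratified by pump speed,
floor-rounded with remainders to train. The default layout is two hidden
layers of 64; `select_architecture` reproduces the selection criterion
(smallest parameter count within 5% of the best validation loss) over any
candidate list. Training is seeded and reproducible; headline error
metrics in the acceptance suite are averaged over three training seeds.

## Evaluation conventions

- error = |predicted − exact| per sample; 95% CI = mean ± 1.96·SD/√n
  (normal approximation); relative error = mean over samples of
  |error|/exact. The per-sample convention is the only one numerically
  consistent with jointly reported mean error, mean exact value and
  relative error on skewed populations, which the tests pin down.
- Hemodynamic summaries are read from the final 5 s window: LVEDV/LVESV are
  the LV-volume extremes over the window (a single cardiac cycle is *not*
  used, because under the 2 s speed modulation single-cycle extrema depend
  on the arbitrary beat/pulse phase alignment); LVEDP is the LV pressure at
  the LVEDV instant; LVESP is the peak LV pressure; PCWP is the
  time-averaged pulmonary venous pressure, the standard 0D surrogate for
  wedge pressure; LVEF = 100·(LVEDV − LVESV)/LVEDV.

## Scales and what the tests show

Full scale (21 speeds × 10,000 samples) is hours of CPU; the shipped
presets are `tiny` (2 × 20, smoke), `small` (5 × 500, desk) and `full`.
The acceptance suite runs the population hemodynamics at 500 draws across
the 5-speed grid and the end-to-end inverse problem at the small preset;
at that scale label recovery is characteristically ordered (the passive
stiffness k_E,lv recovered far best, the baroreceptor gain G_Emax,lv
worst — the model is least sensitive to it) with mean relative errors
within twice the full-scale reference values.

The generator emulates the study conditions exactly (uniform severities,
speed grid, 30 s records, artificial pulse on). It does **not** emulate
measurement noise, sensor drift, valve disease, right-heart failure or
suction events; passing tests therefore demonstrate internal consistency
of the simulator–estimator loop, not clinical performance on measured
pressure waveforms.

## Known limitations

- The circulation constants are a from-memory transcription of the source
  model; small deviations shift the population hemodynamics by a few
  percent (the acceptance bands account for this).
- The pump table is a documented surrogate, not manufacturer data; absolute
  pump flows (hence the exact degree of unloading) are calibration-
  dependent.
- No regurgitant valves, no right-ventricular failure, no suction logic,
  no pump power/current model.
- The estimator is an interpolator over the simulator's manifold: applied
  to waveforms produced by any other mechanism, its outputs are
  extrapolations with no validity guarantee.
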