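# ppgcond

Real-time conditioning of wrist photoplethysmography (PPG) signals with
small LSTM networks that use the accelerometer to undo motion artifacts.

Optical heart-rate sensing on the wrist measures tiny (~2%) changes in
reflected light, and body movement corrupts the waveform badly — a steady
walking cadence of 100 steps/min is nearly indistinguishable from a
heartbeat of 100 bpm. Instead of suspending measurement during movement,
this package trains a recurrent network to *repair* the PPG waveform in
the time domain, using the three accelerometer axes as side information,
so that an ordinary time-domain peak detector can recover the pulse.

## What it implements

- **Synthetic capture protocol** (`ppgcond.synthetic`): ~32 s records at
  32 Hz with movement-free head/tail windows, a quasiperiodic clean pulse
  with known peak times, accelerometer bursts in the walking band
  (0.5–5 Hz), a motion artifact that is a deterministic function of the
  acceleration, and sensor noise.
- **Reference-target construction** (`ppgcond.reference_target`): from
  peak annotations, average the inter-peak periods of the two clean
  windows, T_M = (T_A + T_B)/2; count the beats bridging the gap,
  n = (t_B − t_A)/T_M with n rounded half-up; fill the gap with
  linearly ramped intervals T_i = T_A + 2i((t_B − t_A)/⌊n⌋ − T_A)/(⌊n⌋+1)
  that sum exactly to the gap; lay a cosine with a maximum at every peak
  and compress its negative lobe by G = 0.3 (PPG pulses are
  bottom-flattened), then normalize to [−1, 1].
- **Sequence datasets** (`ppgcond.dataset`): length-L windows with
  inter-sample stride S over the 4 channels, paired with the target value
  at the window's last sample.
- **LSTM conditioner** (`ppgcond.lstm`): 1–2 LSTM layers of N_h cells
  plus a linear output, written in NumPy (forward, backprop-through-time,
  Adam, MAE loss), with a 240-variant hyperparameter grid
  (L ∈ {4,8,16,24,32}, S ∈ {1,2,4,8,10,16}, N_l ∈ {1,2}, N_h ∈ {4,8,16,32}).
- **Evaluation** (`ppgcond.evaluate`): zero-phase Butterworth bandpass
  (0.5–4 Hz, applied forwards and backwards), refractory-constrained peak
  detection, and the sliding-window heart-rate MAE protocol (8 s windows,
  2 s shift, error in bpm).
- **Cost model** (`ppgcond.cost_model`): analytic operation counts per
  LSTM timestep weighted by measured relative costs (add 1, multiply 1.2,
  divide 3, exp 15; sigmoid expands to 20 units, tanh to 36), for ranking
  variants by computational expense.

## Worked example

```python
import ppgcond as pc

result = pc.denoising_experiment(seed=1)
print(f"raw HR MAE          {result.hr_mae_raw:.3f} bpm")
print(f"conditioned HR MAE  {result.hr_mae_conditioned:.3f} bpm")
print(f"MSE-to-target drop  {result.mse_reduction_pct:.1f} %")
```

This generates 112 motion-corrupted synthetic records, trains the
L=4, S=2, N_h=8, N_l=1 variant on 100 of them, and scores the 12
held-out records. It prints:

```
raw HR MAE          0.262 bpm
conditioned HR MAE  0.134 bpm
MSE-to-target drop  96.9 %
```

The conditioned signal roughly halves the heart-rate error of the raw
motion-corrupted signal and removes ~97% of the waveform's squared error
against the clean target — the package's desk-scale reproduction of the
conditioning effect.

The command-line tool mirrors the library:

```
ppgcond generate --n-records 4 --seed 3 --out-dir data/
ppgcond build-targets --records data/rec0000.csv --annotations data/rec0000.peaks.csv --out-dir targeted/
ppgcond cost --l 4 --s 2 --nh 8 --nl 1
```

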