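# Methods

## Signal model and capture protocol

A record couples one PPG channel with three accelerometer axes, all
sampled at 32 Hz for ~32 s (1024 samples). The wearer holds still for a
few seconds at the head and the tail of the record; these two
movement-free stretches (Time Window A and Time Window B) are the only
parts where peak detections are trusted. Time is seconds; sample index k
corresponds to time k/32 (0-based). Every channel is normalized
per record by an affine min–max map onto [−1, 1] (minimum → −1,
maximum → +1), with the offset/scale stored so the map is invertible; a
constant channel maps to zeros with scale recorded as 0 rather than
erroring, so degenerate synthetic inputs flow through the pipeline.

## Reference-target construction

The supervised target is an idealised PPG built from the peak
annotations alone:

1. T_A is the interval between the last two peaks of Window A, T_B
   between the first two of Window B, and T_M = (T_A + T_B)/2.
2. With t_A the last peak of Window A and t_B the last peak of Window B,
   the gap holds n = (t_B − t_A)/T_M beats. n is rounded **half-up**;
   the rounding deviation |n − round(n)| ≤ 0.5 is the validity test,
   with the boundary counting as valid. Because half-up rounding makes
   the deviation ≤ 0.5 for every real n, the literal test never rejects;
   `build_reference` therefore exposes the bound as a parameter
   (`max_dev`, default 0.5) so a stricter screen can be applied.
3. The gap is filled with intervals
   T_i = T_A + 2i((t_B − t_A)/round(n) − T_A)/(round(n) + 1),
   i = 1..round(n), which are linear in i and sum *exactly* to
   t_B − t_A (an algebraic identity, asserted to 1e−9 s). Their
   cumulative sums insert round(n) − 1 interior peaks and land on t_B;
   the interior detections between the windows are replaced by this
   grid.
4. Through the Window-A peaks plus the filled grid a piecewise cosine is
   laid with value +1 at every peak and one full period per beat;
   outside the first/last peak the adjacent period is extended (a
   choice — the construction is unspecified there). The negative lobe is
   compressed by G = 0.3 (configurable), mimicking the bottom-flattened
   shape of a real pulse, and the result is min–max normalized.

**Validity domain.** The linear interval ramp is exact for a constant
heart rate and approximates a drifting rate to second order: the maximum
waveform recovery error grows roughly quadratically with the drift
(≈0.004 full-scale units at 1 bpm drift per 32 s record, ≈0.014 at
2 bpm, ≈0.09 at 5 bpm). The construction is therefore only meaningful
for records captured at rest, which is what the protocol prescribes.

## Synthetic data generator

The generator emulates the capture protocol so every downstream stage is
testable with known ground truth. Defaults are the protocol's
conditions: 32 s at 32 Hz, 5 s clean head and tail, heart rate starting
at 70 bpm and drifting ~2 bpm across the record (a seated subject;
larger drifts leave the reference construction's validity domain, see
above), artifact gain 1.0, sensor-noise SD 0.02 full-scale units.

- True peak times come from integrating a linearly drifting
  instantaneous rate and inverting the phase in closed form.
- The clean pulse is exactly the reference shape (flattened cosine
  through the true peaks), which makes target recovery testable to
  sampling granularity.
- Accelerometer bursts are sums of 2–5 sinusoids drawn from 0.5–5 Hz —
  the walking/arm-swing band that overlaps the heart-rate band, the
  hard case for artifact removal — confined to the middle segment by a
  smooth cosine-tapered envelope that is exactly zero inside the clean
  windows.
- The PPG artifact is a deterministic function of the accelerometer
  channels: a random (seed-derived) linear mix of the three axes plus an
  amplitude modulation of the pulse by the summed |acceleration|. With
  the same seed, records are bit-identical; with artifact gain 0 the PPG
  differs from the clean pulse only by noise.

What the generator does **not** emulate: dicrotic notches and other
morphological detail, sensor-optics nonlinearity, baseline wander from
respiration, or non-stationary artifact coupling. Passing tests on this
corpus demonstrate that the pipeline's mechanics work and that the
network can exploit an accelerometer-coupled artifact; they do not
certify accuracy on real wrist data.

## Sequence datasets

A training sequence of length L with inter-sample stride S ending at
sample e takes samples e−(L−1)S, …, e−S, e from the four channels
(fixed feature order ppg, acc_x, acc_y, acc_z) and is paired with the
*target value at e* — the causal pairing a real-time conditioner
requires; centre- or next-sample pairing would anticipate the future.
Consecutive sequences advance by hop = 1 by default (continuous
inference needs hop 1 anyway). A sequence spans (L−1)·S + 1 raw
samples. Splits are at record level only, because hop-1 windows overlap
heavily and a sequence-level split would leak evaluation data into
training.

## Conditioning network and training

Architecture: 1 or 2 LSTM layers of N_h cells with forget gates,
followed by a linear fully connected unit emitting one value per
sequence. The implementation is plain NumPy: a vectorised
forward pass, backpropagation through time (gradients verified against
central finite differences to ~1e−10), and Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8) minimising mean absolute error. Input kernels are
Glorot-uniform, recurrent kernels block-orthogonal, biases zero except a
unit forget-gate bias; all draws derive from the config seed and
training is deterministic for a fixed seed.

Unstated training details are fixed as: batch size 32, learning rate
1e−3, both exposed in `ModelConfig`. The evaluation loss is the MAE
averaged per evaluation record and then across records, and the weights
retained are those of the epoch with the best evaluation loss. Training
saturates well before 60 epochs on the synthetic corpus; the desk-scale
experiment uses 30.

At inference the record is left-padded with its first sample's values
for the (L−1)·S samples that lack a full history, segmented with hop 1,
and predicted per sample; outputs are clipped to [−1, 1].

The hyperparameter grid (L ∈ {4,8,16,24,32}, S ∈ {1,2,4,8,10,16},
N_l ∈ {1,2}, N_h ∈ {4,8,16,32}) enumerates 240 variants; `run_grid`
trains any sub-grid at reduced epochs and joins the analytic cost to
each variant's best evaluation loss.

## Peak detection and heart-rate scoring

The conditioned PPG is band-passed at 0.5–4.0 Hz (30–240 bpm) with an
overall order-8 Butterworth filter applied forwards and backwards, so
the magnitude response is squared and the phase cancels — peak positions
are preserved. Peaks are then local maxima separated by at least a
0.25 s refractory interval (240 bpm ceiling; the larger of two close
maxima wins) and above 0.3× a running amplitude envelope (moving maximum
of |x| over 2 s). This detector is a deliberately simple, clearly
parameterised stand-in for a production time-domain detector; results
are comparable in protocol, not in detector internals.

Heart rate in a window is 60 / (mean inter-peak interval) over the peaks
inside it (median optional), undefined with fewer than two peaks.
Accuracy is the mean absolute error in bpm over sliding windows of 8 s
shifted by 2 s; windows where either train defines no rate are excluded
and counted. Corpus aggregates are mean ± SD of per-record MAEs.

## Cost model

Feasibility on a wearable is estimated by counting basic operations per
inference, weighted by relative costs measured on an embedded ARM
platform (add 1, subtract 1, multiply 1.2, divide 3, exp 15). Sigmoid
and tanh are expanded literally from their exponential forms: sigmoid =
1/(1 + e^(−x)) → 1 negate + 1 exp + 1 add + 1 divide = 20 units; tanh =
(e^x − e^(−x))/(e^x + e^(−x)) → 2 exp + 2 subtract + 1 add + 1 divide =
36 units (a negation counts as one subtract; e^x and e^(−x) count as two
exp calls). Per timestep with input width d and hidden size h, the four
gates cost h(d+h) multiplies and h(d+h) adds each, plus 3h sigmoids and
h tanh; the cell update adds 2h multiplies + h adds; the hidden update
h tanh + h multiplies. A variant is costed with the flattened
convention d = 4L, h = N_h·N_l over L timesteps plus the output head
(h multiplies + h adds); this approximates two-layer networks, so an
exact per-layer mode (layer 1: d = 4; deeper layers: d = N_h) is
provided as an explicitly non-default option. The closed form is
verified operation-for-operation against an instrumented scalar
execution of the recurrence.

## Desk-scale experiment sizes

The denoising experiment trains the L=4, S=2, N_h=8, N_l=1 variant for
30 epochs on 100 records (~102k sequences) and evaluates on 12 held-out
records; it completes in well under a minute on one CPU. The
acceptance script additionally sweeps 1000 random gap geometries, 20
recovery records, and the 16 (d, h) cost cross-checks.

## Known limitations

- The gap-validity test, implemented literally with half-up rounding,
  cannot reject; screening requires the stricter `max_dev` bound.
- The reference construction (and hence the generator's default drift)
  assumes a near-constant heart rate per record.
- The peak detector is a stand-in; no claim is made about parity with
  production time-domain detectors.
- The cost model counts arithmetic only — no memory traffic, no
  fixed-point effects, and the flattened d = 4L convention intentionally
  mirrors a published accounting rather than exact per-layer counts.
- Real-data accuracy (e.g. on multi-hour daily-living datasets) is out
  of scope here; only the protocol, not the published error tables, is
  reproduced.
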