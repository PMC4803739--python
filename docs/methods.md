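# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the tests do and do not establish.

## Stimuli

Three families, all parameterised by fundamental frequency F0:

* **Harmonic complex** — `Σ_k a_k sin(2π k F0 t)` for `k = 1..10`
  (`pure` is the `k = 1` case). Sine phase, zero offset for every
  component: deterministic and standard for complex-tone work.
* **Missing fundamental (MF)** — the same sum for `k = 2..10`.
* **Iterated rippled noise (IRN)** — Gaussian broadband noise passed
  through a delay-and-add circuit: delay `d = 1/F0` (rounded to the
  nearest whole sample), 30 iterations by default. The default circuit
  is *add-same* (the accumulated signal is re-delayed each iteration);
  *add-original* is available behind a keyword because the two variants
  differ in pitch strength. Unity gain per iteration. IRNs are kept
  broadband (white to the Nyquist frequency); no band-limiting to the
  trained harmonic range is applied.

Harmonic amplitudes follow the decay envelope `a_k = exp(-k·F0/τ)`,
applied to every included component including F0 itself; `τ = None`
denotes a flat profile. The fixed-profile ladder used in experiments is
`τ ∈ {F0, (10/3)F0, 5F0, 10F0, flat}`. (One published description of
the boundary profile prints the envelope exponent with a positive sign;
that form is not a decay and contradicts the envelope definition used
everywhere else, so the boundary profile is implemented as `τ = 10·F0`.)

Calibration scales the waveform so the RMS of the central, un-ramped
portion equals `20 µPa · 10^(L/20)` for level `L` dB SPL (default 50),
then applies raised-cosine onset/offset ramps (default 10 ms). Duration
and sample rate default to 200 ms at 50 kHz — long enough for stable
rate averages, with Nyquist headroom for the 6 kHz top harmonic of the
600 Hz / 10-harmonic case. All generators are pure functions of
(spec, seed).

## Built-in auditory-nerve front-end

The front-end is intentionally minimal: it supplies the one feature the
network learns from — a tonotopic excitation pattern with resolved low
harmonics and merged high harmonics — and nothing else. Per channel at
characteristic frequency CF:

1. 4th-order gammatone **magnitude** response, unit peak gain, bandwidth
   `1.019 · ERB(CF)` with `ERB(f) = 24.7 (4.37 f/1000 + 1)` Hz. The
   filter is applied zero-phase (magnitude only).
2. Half-wave rectification.
3. Power-law compression, exponent 0.3 (configurable).
4. Time average over the full stimulus.
5. **Hearing-threshold floor**: the mean compressed response a 0 dB SPL
   tone would evoke at its best channel is subtracted and the rate
   clipped at zero. Without the floor, the power law assigns rates of
   ~0.2 to channels 60 dB below the stimulus; the resulting common
   plateau makes rate vectors of different F0s nearly collinear
   (adjacent-F0 cosine 0.98) and competition cannot separate them.
6. Across-fiber normalization, **unit L2 length by default**. Peak
   (max = 1) normalization is available as `normalization="max"` and is
   the default contract of `normalize_rates` itself. Unit length is the
   pipeline default because it keeps the Hebbian update commensurate
   with the unit-norm weight rows: with peak normalization the input
   norm is ~30, a single update (`k‖r_out‖‖r_in‖ ≈ 7.5` against row
   norm 1) completely overwrites a winner's tuning, and training
   collapses to a handful of winner blocks. With unit-length inputs an
   update blends ~20 % of the new pattern into a row, and the map
   refines to per-stimulus winner groups.

Spontaneous rate is zero; there is a single fiber class. Channels above
the Nyquist frequency report zero rate with a warning. Silence returns
an all-zero vector with a warning instead of an error.

For strictly periodic tone complexes the zero-phase filter output is
itself periodic with period 1/F0, so the steady-state rate is computed
exactly on one densely sampled period (`tone_complex_rates`), excluding
the onset/offset transients; this path agrees with the full waveform
path to ~2 % (the ramp contribution) and is ~100x faster, which is what
makes the random-decay regime (2100 distinct stimuli per run) cheap.

Externally computed rates (e.g. from a full phenomenological periphery
model) enter through `adapter_rates`, which validates length and
finiteness and applies the same normalization. The built-in model
deliberately omits that phenomenology — no saturation, no adaptation,
no middle-ear transfer, no phase locking (see Limitations).

## Network

`h = W r`; shared threshold `α` = the m-th highest activation with
`m = round(a · n_out)` (exactly 20 for the defaults), recomputed every
presentation; logistic output with gain `2β`; online Hebbian update
`ΔW = k · outer(r_out, r_in)` after each presentation, followed by
rescaling every row to unit L2 norm. All output cells learn with their
post-sigmoid rates — there is no hard winner-take-all mask, losers
simply contribute their small rates. Ties at the threshold rank are
resolved by the sigmoid itself (tied cells sit at rate 0.5); the
activity record flags presentations where ties inflate the winner
count. Weight init: uniform(0,1) entries, rows normalized. Weight init
and epoch shuffling draw from separate, independently seeded streams,
so the init seed can be varied with the presentation order held fixed
(the design used for seed-comparison analyses). The sigmoid argument is
clamped at ±700 before exponentiation — a floating-point guard with no
semantic effect.

Defaults (`NetworkParams`): 2500 inputs, 200 outputs, `k = 0.25`,
`β = 17.45`, `a = 0.10`, 50 epochs; the random-decay regime uses 100
epochs (the regime-specific value overrides the general default).

## Experiments and decoding

An epoch presents all 21 stimuli once in a fresh random order (plain
permutation). Testing (`test_network`) never updates weights. Response
maps order rows by F0; heatmaps sort cells by the stimulus index of
their peak rate, ties broken by cell index.

The published results are read off sorted heatmaps by eye; to make the
claims testable a deterministic **label-vote decoder** is used: each
cell is labelled with the training F0 at which it fires maximally; a
test sound is decoded as the label with the largest summed rate among
cells at or above the sigmoid midpoint (0.5), ties broken by total
summed rate, then by lower F0; a sound activating no cell decodes as
undetermined. Accuracy is the fraction of probes decoded within ±1 grid
step (±20 Hz), counting undetermined as errors — the tolerance that
matches "identifies the pitch" on a 20 Hz grid.

## Single-cell information

Rates are binarized at 0.5 — strictly greater means active; a cell at
exactly 0.5 is sitting on the competition threshold and counts inactive.
Responses are deterministic given a stimulus, so `P(r|s) ∈ {0,1}` and,
under a uniform prior over the N presented stimuli (each presented
once), `P(r)` is the column frequency of the observed state; then
`I(s,R) = -log2 P(r_s)` with `0·log 0 := 0`, in bits, bounded by
`log2 N`. The ranked single-cell curve uses max-over-stimuli per cell
(mean available as an option); the per-stimulus profile is max over
cells.

## Problem sizes and determinism

Every experiment is a pure function of its master seed (child streams
for init / shuffle / decay draws / IRN noise). The test suite runs the
full-scale system — 2500 fibers, 200 cells, 50- or 100-epoch trainings —
using 10 weight-init seeds for the population-level claims and a single
shared decay-draw stream across those seeds; the whole suite completes
in a few minutes on one CPU because tone-complex rates use the
steady-state fast path and rate vectors are computed once per stimulus
battery, not per seed.

## Known limitations

* The front-end is an excitation-pattern model, not a periphery model:
  no rate saturation, no power-law adaptation, no middle-ear rolloff,
  no spontaneous-rate classes, no temporal fine structure. Passing
  tests show the competitive-learning claims hold for this idealized
  place code; they do not certify behavior under realistic nerve
  phenomenology, which is what the adapter contract is for.
* IRN transfer is the casualty of that simplification. Training sounds
  are band-limited (10 harmonics, ≤ 6 kHz) while IRNs are broadband:
  about half of an IRN rate vector's energy lies above 6 kHz, and the
  dense high-harmonic energy of low-F0 IRNs overlaps the tuning of
  high-F0 cells, so decoded IRN pitches compress toward the upper end
  of the range. The trained network beats an untrained control on IRN
  decoding above 300 Hz only ~60 % of the time per seed. A periphery
  with saturation and middle-ear filtering compresses exactly this
  high-frequency imbalance; within the built-in front-end the effect
  is structural, and the corresponding population-level check is
  expected to fail more often than not.
* Low fundamentals (< 300 Hz) remain harder than high ones under
  fixed-profile training — their high harmonics crowd together on the
  log axis — and improve under the random-decay regime; this matches
  the qualitative picture the model is meant to exhibit.
* The decoder and the accuracy tolerance are this package's
  operationalization of claims made visually in the source material;
  other readouts (e.g. population vectors) would give different
  absolute numbers.
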