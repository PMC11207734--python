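# gaitsync

Synchronization toolkit for multimodal gait-lab recordings: a photodiode
byte-trigger codec, clock alignment and display-jitter diagnostics,
center-of-pressure (COP) movement-onset detection, and event-locked
EEG/EMG/fNIRS pipelines — exercised end-to-end on a built-in acquisition
simulator.

## The problem

Projection-based gait laboratories (instrumented treadmill, force plates,
motion capture, virtual-reality projection) record alongside independently
clocked neurophysiological systems — mobile EEG, fNIRS, wireless EMG.
Relating a cortical response or a hemodynamic change to a visual stimulus or
a step requires millisecond-grade synchronization, but the display chain
itself delays every stimulus by an unknown amount (frame generation at
60 Hz plus a projector latency), and each acquisition device timestamps on
its own clock.

The approach implemented here marks events *optically*: the control script
blinks a small dot at the screen edge, encoding one event byte per blink
(1 start bit + 8 data bits LSB-first + 1 stop bit, 2 display frames per
bit).  A photodiode picks the blink up from the projection surface, a
Schmitt trigger (comparator with hysteresis) digitizes it, and the decoder
recovers byte and timestamp.  Because the blink traverses the same
projection chain as the stimulus, its decoded time carries the full display
delay — locking analyses to decoded blink times compensates the delay
exactly.  Residual cross-device timing is handled by an affine clock model
`t_to = a + b·t_from` fitted by least squares from shared marker events.

The toolkit also diagnoses the failure mode in which stimulus and blink are
issued by two separate, event-chained scripts: the blink then lags the
stimulus by a *variable* 12–56 ms, which smears event-locked averages.  The
delay report flags any event stream whose delay range exceeds half a frame
period (8.33 ms at 60 Hz).

Downstream analyses:

* **VEP** — band-pass 0.01–40 Hz + 50 Hz notch, common-average reference,
  epochs −500…+400 ms, per-epoch detrend, baseline −500…−100 ms, trial
  average with 95% CI, and N75/P100 peak measures.
* **COP onset** — zero-phase 2nd-order Butterworth at 5 Hz on AP/ML COP,
  per-sample derivatives combined as √(dAP²+dML²); the first crossing of
  0.3 (mm/sample) marks the excursion and the nearest local minimum below
  0.05 is the movement onset.
* **EMG** — DC removal, rectification, centered 100-point moving average,
  epochs −5…+15 s locked to the *kinetic* onsets.
* **fNIRS** — optical density −log10(I/Ī), modified Beer–Lambert conversion
  to ΔHbO₂/ΔHbR (tabulated extinction coefficients, pathlength =
  source–detector distance × DPF), 0.02–0.2 Hz band-pass, short-channel OLS
  regression, onset-locked averages and shape metrics (initial dip, peak,
  return time).

The simulator generates complete synthetic sessions (checkerboard
pattern-reversal and start-to-go step-initiation tasks) with ground truth —
true display times, true onsets, clock parameters — so every stage can be
validated by parameter recovery.

## Worked example

```python
import dataclasses
import gaitsync as g

# simulate a checkerboard session: 120 reversals at 0.5 Hz, 60 Hz display,
# 50 ms projector delay, healthy single-script trigger chain
bundle = g.simulate_session("checkerboard", seed=42)

# decode the photodiode channel and check the display delay
decoded = g.decode_events(g.digitize_schmitt(bundle.stream("photodiode")))
rep = g.delay_report(bundle.events_from("command"), decoded)
print(f"decoded events: {len(decoded)}; delay mean {rep.mean*1e3:.1f} ms, "
      f"range {rep.range*1e3:.1f} ms, jittered: {rep.is_jittered}")

# lock the EEG to the decoded blink times and measure the VEP
lock = g.compensate_display_delay(decoded, bundle.metadata["acquisition_delay_eeg"])
lock = [dataclasses.replace(e, clock_id="eeg") for e in lock]
evoked, peaks, _ = g.vep_pipeline(bundle, lock)
for name, p in peaks.items():
    print(f"{name}: {p.latency*1e3:.0f} ms, {p.amplitude:+.2f} µV")
```

prints

```
decoded events: 120; delay mean 50.0 ms, range 0.0 ms, jittered: False
N75: 66 ms, -5.08 µV
P100: 90 ms, +9.22 µV
```

All 120 byte events decode; their delay against the command times is the
constant 50 ms projector latency with zero spread (nothing to flag), and
the grand-average visual evoked potential shows the N75 negativity near
65 ms and the P100 positivity near 90 ms at its ~9 µV template amplitude —
i.e. the trigger chain is synchronous to within a sample and event-locked
averaging recovers the underlying response.

The same flows are available from the shell:

```sh
gaitsync simulate --task checkerboard --seed 42 --out sess/
gaitsync decode   --in sess/ --out events.json
gaitsync align    --in sess/ --report delays.json
gaitsync vep      --in sess/ --out peaks.json
```

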