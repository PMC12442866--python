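# assrtag

Frequency-tagged auditory steady-state response (ASSR) simulation and
selective-attention decoding.

When a listener hears two simultaneous melodies, each amplitude-modulated
at its own rate (39 Hz for the low-pitched melody, 43 Hz for the
high-pitched one), the brain produces steady-state responses phase-locked
to each envelope. The two responses can be separated in the power
spectrum and — because attention multiplies the attended melody's tag
power — a classifier on the multichannel spectrum can read out *which*
melody the listener attends. `assrtag` is for researchers who want to
run, simulate, or stress-test this analysis: it synthesizes tagged
stimuli, simulates multichannel sensor epochs with a controllable
attention effect, and implements the decoding and statistics stack.

## The method

For conditions *attend-low* vs *attend-high*, the repeated-splitting
decoder estimates, per frequency f:

1. randomly split each condition's epochs into 5 groups, average within
   groups → 5 evoked responses per condition;
2. taper (Hann or boxcar) and Fourier-transform each evoked response at
   1-Hz resolution → power P(channel, f);
3. for each f independently, cross-validate a binary linear SVM on the
   5 + 5 power vectors (channels as features), score by ROC AUC;
4. repeat from step 1 (default 1000×) and average:
   AUC(f) = mean over repetitions.

AUC(f) sits at the 0.5 chance level except where the spectrum carries
condition information — at the stimulus tags 39 and 43 Hz. Downstream
analyses: element-wise best-of-two combination of early/late tone-half
spectra, sliding-window AUC timecourses (1-s window, 50-ms steps), the
peak-attention time and early/late attendee split at 0.5 s, the lateness
index (AUC_late − AUC_early)/(AUC_late + AUC_early), sign-flip and
group permutation tests, Benjamini–Hochberg FDR, Pearson/Kendall
correlations.

See `docs/methods.md` for the model, numerical conventions, and design
decisions.

## Worked example

```python
from assrtag import (ATTEND_LOW, ATTEND_HIGH, DecoderConfig,
                     NeuralSimConfig, repeated_split_auc, simulate_epochs)

sim = NeuralSimConfig(n_channels=20, fs=1000.0, epoch_len=1.0,
                      n_epochs_per_cond=100, attention_gain=2.0, seed=202)
epochs = simulate_epochs(sim, tag_freqs=(39.0, 43.0))

cfg = DecoderConfig(n_repeats=50, window="boxcar", seed=202)
spec = repeated_split_auc(epochs.select(ATTEND_LOW),
                          epochs.select(ATTEND_HIGH), cfg)
print(f"AUC @39 Hz: {spec.at(39.0):.2f}   AUC @43 Hz: {spec.at(43.0):.2f}")
off = [a for f, a in zip(spec.freqs, spec.auc) if f not in (39.0, 43.0)]
print(f"mean off-tag AUC: {sum(off)/len(off):.3f}")
```

prints

```
AUC @39 Hz: 1.00   AUC @43 Hz: 1.00
mean off-tag AUC: 0.496
```

With an attention gain of 2.0 the two conditions are fully separable at
the tag frequencies (AUC = 1.0), while all other bins stay at chance —
the decoder picks up the attention effect exactly where the stimulus put
it. Setting `attention_gain=1.0` (no effect) drives the tag bins to
chance as well.

The same pipeline runs from the shell:

```sh
assrtag simulate --seed 202 --out epochs.h5
assrtag decode epochs.h5 --seed 202 --out auc.csv
assrtag run --config run.yaml        # simulate -> decode -> stats bundle
```

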