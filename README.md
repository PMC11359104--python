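# hivesense

Edge-style beehive condition monitoring in pure scientific Python: the full
analysis stack of a smart-hive detector, from raw in-hive audio and sensor
readings to condition flags and classifier decisions, exercised entirely on
synthetic fixtures.

Beekeepers — especially with migratory apiaries out of network coverage —
need automatic detection of the events that precede colony loss: swarming
build-up, queen loss, starvation, and the abiotic temperature/humidity
regimes that favour Colony Collapse Disorder. `hivesense` implements the
two detection paths such a device runs:

1. **Acoustic path.** A 30–90 s recording (8-bit PCM, 22,050 Hz) is
   low-pass filtered to 0–2.5 kHz, split into 10 s windows (the first is
   discarded), and short-time Fourier transformed (1024-point, hop 256)
   into 513×862 magnitude matrices. Their first 224 rows × 224 frames are
   averaged into the mean response matrix **A**, which becomes (a) the
   grayscale model-input image for a 5-class acoustic classifier and (b)
   the **beegram** — 16 band-mean magnitudes b[0..15] over fixed bands
   from 107 to 687 Hz. Five condition measures with calibrated critical
   limits are derived from it: hunger B_h = (|b₀|+|b₁|)/2, growth
   B_g = mean|b₂..b₇|, queen tone Q_t = max(|b₁₁|,|b₁₂|)+|b₁₅|, thermal
   stress T_h = |b₇|, and swarming
   S_w = ¾·max|b₈..b₁₀| + ¼·max|b₁₁..b₁₄| (flagged when S_w > 0.7, the
   400–500 Hz swarming band).

2. **Sensor path.** Hourly readings from 1–6 brood-frame temperature
   probes plus a lid temperature/humidity sensor are fuzzified with
   bounded-sigmoid, triangular and Gaussian membership functions, combined
   through a 12-rule table (min t-norm, max aggregation, ±25 % rule
   modifiers) into five condition classes (abiotic-cold,
   disease-incubation, normal, abiotic-hot, outlier), and classified by a
   **stranded** dense network: one small net per flattened batch size
   24·(probes+2) ∈ {72, …, 192}, selected at inference time by probe
   count. The default 96- and 144-input strands have exactly 12,581 and
   45,509 trainable parameters.

Training uses Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8), categorical
cross-entropy, batch 64, 100 epochs, an 80/20 split and an L1 penalty of
0.005 per dense layer; training health is judged by the convergence-speed
rate Conv = (Acc_n − Acc_k)/(n − k + 1) at epoch breakpoints 20/50/100.
Because no public corpus of hive recordings or probe data exists, the
package ships class-conditioned synthetic generators (band-structured
audio, fuzzy-verified sensor days) that every test runs on — see
`docs/methods.md` for what they do and do not emulate.

## Worked example

```python
import numpy as np
import hivesense as hs

# a 60 s synthetic recording with swarming-band (400-500 Hz) energy
rec = hs.gen_audio_class(4, duration=60.0, seed=11)      # class 4: late-swarm
result = hs.process_recording(rec)                        # filter -> STFT -> 224x224
vec = hs.extract_beegram(result.mean_response)            # 16 band means
measures = hs.compute_measures(vec)

print(f"windows averaged : {result.n_windows}")
print(f"beegram b[8..10] : {np.round(vec.b[8:11], 3)}")
print(f"Sw measure       : {measures.Sw:.3f}  (critical > 0.7)")
print(f"flags            : {[k for k, v in measures.flags.items() if v]}")

# train the 2-probe strand on a small fuzzy-annotated sensor dataset
X, y = hs.gen_dataset(per_class=500, n_probes=2, seed=0)
model, metrics = hs.train_strand(hs.build_strand(2, seed=0), X, y,
                                 hs.TrainConfig(epochs=20, seed=0))
print(f"strand params    : {model.n_params}")
print(f"held-out accuracy: {model.holdout_accuracy:.1f}%")
label, proba = hs.StrandedClassifier({96: model}).infer(X[0])
print(f"day 0 prediction : {label.name} (p={label.confidence:.2f})")
```

prints

```
windows averaged : 5
beegram b[8..10] : [0.851 0.964 0.844]
Sw measure       : 0.825  (critical > 0.7)
flags            : ['Bh', 'Bg', 'Sw']
strand params    : 12581
held-out accuracy: 96.0%
day 0 prediction : abiotic-cold (p=0.99)
```

The synthetic late-swarm recording concentrates its energy in beegram
bands 8–10 (≈400–500 Hz), pushing the swarming measure past its 0.7 limit;
the hunger/growth flags are the low-side flags expected of a tone-only
recording with no broadband brood hum. The 2-probe strand recovers the
five sensor classes at 96 % held out after 20 epochs on 2,500 days; the
first day of the dataset belongs to the cold class and is predicted as
such with probability 0.99.

A command-line interface mirrors the device workflow:

```sh
hivesense synth --out fixtures --seed 3 --per-class 100 --probes 2
hivesense train-strand --out models --probes 2 --per-class 16000
hivesense detect-conditions fixtures/sensor_days_seed3.csv --model models --probes 2
hivesense train-audio --out models/audio --per-class 100
hivesense detect-audio fixtures/audio_class4_late-swarm_seed7.wav --model models/audio
```

Every emitted JSON record carries the seed, a config hash and the package
version, so runs are reproducible.

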