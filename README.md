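# itcdecode

Multi-scale category decoding of simulated inferotemporal cortex recordings.

## The problem

Neurons in primate inferior temporal cortex (ITC) are selective for visual
categories at several levels of a hierarchy — coarse categories such as
*face* / *body* / *inanimate object*, and finer facial subcategories
(species, viewing angle, identity). Recording techniques differ in how much
cortex each channel integrates: multi-unit activity (MUA) reflects spiking
within ~100 µm of a microelectrode tip, local field potentials (LFP) sum
synaptic currents over hundreds of micrometers, and surface ECoG contacts
sum over millimeters. Comparing category decoding across simultaneously
recorded MUA, LFP, and ECoG therefore probes the *spatial organization* of
category-selective activity: information carried by spatially homogeneous,
long-range activity patterns survives (or is enhanced by) summation, while
information carried by fine, salt-and-pepper patterns is averaged away.

The real recordings behind this research question are not publicly
deposited, so `itcdecode` pairs the complete analysis stack with a
synthetic-data generator that emulates category-tuned multichannel
recordings at the three summation scales, with known ground truth. Every
analysis stage is testable against the generative parameters.

## What is inside

- **`synthetic_data`** (`config`, `stimuli`, `tuning`, `simulate`): a
  6 × 10 electrode grid at 1.2-mm pitch with a half-pitch-offset surface
  grid; a hierarchical stimulus set (3 coarse categories; faces split into
  2 species; human faces a full 3-view × 5-identity block); Gaussian-field
  category tuning maps with long correlation length for coarse categories
  and short for subordinate ones; stimulus-locked theta (4 Hz) "evoked"
  components, non-phase-locked high-gamma (80 Hz) "induced" components,
  spikes coupled to the local gamma envelope, and shared plus private noise.
- **`signal_features`** (`spikes`, `spectral`, `features`, `extract`):
  3.7 × SD threshold-crossing spike detection; spike density functions with
  Shimazaki–Shinomoto-optimized Gaussian kernel bandwidth; KS-based
  visual-responsiveness screening; 100-ms/50-ms windowed spike rates; FFT
  "total power"; Morlet wavelet band power (σ = one cycle period, 2σ
  truncation); prestimulus normalization and 50–450-ms band responses.
- **`decoding`**: pairwise linear-SVM decoding with training-set
  z-scoring, top-100 F-statistic feature selection, class balancing to a
  50% chance level, and exemplar-held-out cross-validation (all trials of a
  stimulus confined to one side of each fold, so accuracy measures category
  generalization, not image memorization); time-resolved and
  frequency-resolved variants.
- **`shuffle`**: spatial shuffling of channel labels within subareas of
  4–60 channels with the decay fit *y* = A·exp(−Bx) + C (A > 0, B > 0,
  C > 50); trial shuffling that destroys cross-channel covariance while
  preserving per-channel marginals; chi-squared condition comparisons.
- **`maps` / `phase`**: split-half d′ selectivity maps (odd trials pick the
  preferred category, even trials measure d′), |d′| > 1 selective-channel
  counts with Fisher's exact test, cross-modality selectivity correlations,
  classical MDS embeddings, and cross-channel theta phase-locking values
  (PLV) at 75 ms post-onset with rank-based category tests.
- **`cli_io` / `pipeline`**: HDF5 session containers, a validated pipeline
  config, a manifest with per-stage artifact hashes, and the `itcdecode`
  CLI (`simulate`, `features`, `decode`, `shuffle`, `maps`, `report`).

## Worked example

```python
import itcdecode as itc
from itcdecode import extract

cfg = itc.SimConfig(seed=1)                    # default study conditions
stim = itc.make_stimulus_set(cfg)
maps = itc.generate_tuning_maps(cfg, stim)     # ground-truth tuning fields
ses = itc.simulate_session(cfg, stim, maps)    # 60 ch x ~328 s, 312 trials

tables = {
    "ecog": extract.total_power_from_session(ses, stim, "ecog"),
    "lfp":  extract.total_power_from_session(ses, stim, "lfp"),
    "mua":  extract.spike_rate_features(ses, stim),
}
for mod, table in tables.items():
    for level in ("coarse", "identity"):
        res = {p: itc.pairwise_decode(itc.DecodeSpec(level, p, seed=0), table)
               for p in itc.level_pairs(level)}
        print(mod, level, f"{itc.level_accuracy(level, res):.1f}%")
```

Output (seed 1):

```
ecog coarse 97.2%    ecog identity 59.0%
lfp  coarse 99.0%    lfp  identity 82.5%
mua  coarse 78.1%    mua  identity 81.5%
```

Read this as the summation-scale dissociation the package exists to study:
coarse (face/body/object) information is carried by a spatially homogeneous
field, so the heavily summating surface array decodes it best, while
identity information lives in fine-grained patterns that summation averages
away — ECoG identity decoding sits near chance while MUA and LFP retain it.

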