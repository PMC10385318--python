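# epifed

Patient-specific preictal-state prediction from multichannel EEG, built as a
reusable pipeline:

1. **Preprocessing** — second-order zero-phase Butterworth bandpass
   (default 0.5–40 Hz), per-second sliding-window z-normalization, and
   correlative channel selection (two-level fractional-factorial screening +
   backward wrapper elimination).
2. **Segmentation** — sliding windows at four timescales (1/2/4/8 s),
   exactly class-balanced training-sample generation (majority class without
   overlap, minority class with the largest overlapping stride that matches
   the majority count), and ROC-AUC-based *bi-timescale* selection of the two
   best window lengths.
3. **Spiking encoder** — binary spike matrices from per-channel up/down
   thresholds, run-length spike statistics, a per-channel seizure indicator
   (many spikes AND short durations → High), logical-AND fine tuning, and a
   fast-sigmoid surrogate gradient through a trainable threshold offset.
4. **Graph model** — channel graph from thresholded |Pearson| correlations,
   symmetric renormalization `D̃^(-1/2)(A+I)D̃^(-1/2)`, and a two-layer
   gated graph-convolutional classifier (16+16 units, GELU/Tanh/Sigmoid,
   Adam, dropout 0.2) whose two timescale branches are concatenated before a
   softmax head. Implemented in NumPy with hand-written backprop.
5. **Federation** — simulated cross-hospital FedAvg with
   divergence-regularized personalization: each client minimizes
   `w1·CE + w2·KL(P̄_G‖P_P)` where the global preictal probability is
   damped on clients whose spiking indicator saw few High segments;
   early stopping on pooled validation loss retains the best round.
6. **Risk staging** — 3-input/3-MF/27-rule first-order Sugeno ANFIS over
   (EEG probability, HRV composite, clinical composite), hybrid least-squares
   + gradient training with PSO over premise initializations, HRV
   transition-pattern staging (alpha/beta/gamma → Pk1/Pk2/Pk3), and
   preictal-start / alarm-onset / SPH localization.
7. **Evaluation** — sensitivity/specificity/accuracy/FPR, relative accuracy
   against the majority-class baseline, rank-statistic ROC AUC, and
   leave-one-subject-out cross-validation.
8. **Synthetic data** — seeded multi-hospital EEG/HRV/clinical generators
   with planted class structure (short frequent preictal bursts vs long rare
   interictal ones; alpha/beta/gamma HRV transition patterns; per-class
   clinical ranges), so the whole pipeline is testable offline.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalences,
planted-recovery bounds, and the 5-seed end-to-end synthetic run); the rest
are unit/property tests per module. The full suite takes ~6 minutes on one
CPU.

## CLI

```bash
# seeded synthetic multi-hospital dataset (EEG CSV + JSON sidecar,
# annotations CSV, HRV CSV, clinical JSON)
epifed simulate --spec spec.json --out data/

# preprocessing
epifed preprocess --in data/hospital0 --out prep/ --low 0.5 --high 40 --order 2 --window 1.0

# balanced segmentation + bi-timescale selection
epifed segment --in data/hospital0 --out segs/ --scales 1,2,4,8 --select-bi

# full pipeline: preprocess -> bi-timescale -> federated spiking-GCNN -> report
epifed run --in data/ --out report.json

# metrics from a predictions CSV against annotation tables
epifed evaluate --pred pred.csv --truth data/hospital0 --out metrics.json

# fine-grained risk staging for one subject
epifed personalize --predictions pred.csv --hrv subj_hrv.csv \
    --clinical subj_clinical.json --seizure-onset 2000 --out risk.csv
```

## Data formats

* **EEG**: numeric CSV (rows = samples, columns = channels; optional header)
  plus a JSON sidecar `{"fs": ..., "channels": [...]}` and an annotations CSV
  `state,start_s,end_s` with states in {preictal, interictal, ictal}. All
  intervals are half-open `[start, end)` seconds.
* **HRV**: CSV `time_s,Lmax,SDNN,LF_HF,MeanHR,pNN50`.
* **Clinical**: JSON with age, gender, genetic/metabolic flags, and seizure
  event count.
* **Predictions**: CSV `subject_id,window_start_s,window_end_s,`
  `preictal_probability,predicted_state`.
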