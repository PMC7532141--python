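"""Featurize a multi-electrode EEG recording: montage then MFCCs.

A 5-minute, 250 Hz synthetic recording over the standard electrode set is
re-referenced onto the 22-pair bipolar TCP montage and converted per channel
into 40 mel-frequency cepstral coefficients (resample to 100 Hz, 2000-point
FFT frames every 100 samples), stacking to 880 feature channels.
"""

from chronodense import SynthSpec, eeg_mfcc_features, gen_eeg_like, tcp_montage

spec = SynthSpec(task="eeg-like", n_samples=1, n_classes=1,
                 sequence_length=75_000, noise_sigma=0.3, seed=0)
recordings, electrode_names, labels = gen_eeg_like(spec, sampling_rate=250.0)
print(f"raw recording: {recordings.shape[1]} electrodes x "
      f"{recordings.shape[2]} samples at 250 Hz")

montaged = tcp_montage(recordings[0], electrode_names)
print(f"TCP montage: {montaged.shape[0]} bipolar channels")

features = eeg_mfcc_features(montaged, source_rate=250.0)
print(f"MFCC tensor: {features.shape[0]} channels x {features.shape[1]} frames")
print("880 = 22 montage channels x 40 cepstral coefficients; 301 frames = "
      "1 + 30000 resampled samples / 100-sample hop.  This tensor is the "
      "model input for EEG abnormality detection.")
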