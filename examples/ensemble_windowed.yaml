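# Excitation-energy-restricted ensemble (0.14 eV window centred at
# 6.59 eV), mimicking a fixed-wavelength pump pulse.
n_trajectories: 64
seed: 7
n_wigner_samples: 2000
window: [6.52, 6.66]
include_triplets: true
propagator:
  t_max_fs: 1000.0
output_dir: runs/ensemble_windowed
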