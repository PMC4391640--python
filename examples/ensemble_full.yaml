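# Full-spectrum production ensemble: 120 trajectories, 1 ps, IC + ISC.
n_trajectories: 120
seed: 7
n_wigner_samples: 2000
include_triplets: true
propagator:
  dt_fs: 0.5
  dt_electronic_fs: 0.02
  t_max_fs: 1000.0
  decoherence_alpha: 0.1
spectrum_fwhm_ev: 0.1
output_dir: runs/ensemble_full
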