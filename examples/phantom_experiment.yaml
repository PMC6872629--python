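seed: 0
phantom:
  image_size: 128
  n_control: 15
  n_diseased: 15
  lesion_amplitude: 3.0
  lesion_radius: 8.0
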