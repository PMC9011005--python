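# Qualitative IRSE, ACR-style phantom imaging
name: irse_acr
kind: irse
fov: 0.25
matrix_n: 256
n_slices: 11
slice_thickness: 0.005
tr: 2.0
te: 0.012
ti: 0.150
flip_excitation_deg: 90
flip_refocus_deg: 180
quantitative: false
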