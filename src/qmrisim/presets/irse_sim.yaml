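# Low-resolution simulation IRSE (TR 4500 / TI 200 / TE 10 ms)
name: irse_sim
kind: irse
fov: 0.25
matrix_n: 32
n_slices: 1
slice_thickness: 0.005
tr: 4.5
te: 0.010
ti: 0.200
flip_excitation_deg: 90
flip_refocus_deg: 180
quantitative: false
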