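# Qualitative TSE, ACR-style phantom imaging (effective TE = 50 ms, 4 echoes)
name: tse_acr
kind: tse
fov: 0.25
matrix_n: 256
n_slices: 11
slice_thickness: 0.005
tr: 3.0
te: 0.050
etl: 4
center_echo: 2
flip_excitation_deg: 90
flip_refocus_deg: 180
quantitative: false
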