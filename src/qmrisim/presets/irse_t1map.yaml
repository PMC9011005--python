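# 10-TI IRSE T1-mapping protocol (sagittal NIST-like T1 plane)
name: irse_t1map
kind: irse_t1map
fov: 0.25
matrix_n: 128
n_slices: 1
slice_thickness: 0.006
tr: 4.5
te: 0.010
ti_list: [0.050, 0.075, 0.100, 0.125, 0.150, 0.250, 1.000, 1.500, 2.000, 3.000]
flip_excitation_deg: 90
flip_refocus_deg: 180
quantitative: true
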