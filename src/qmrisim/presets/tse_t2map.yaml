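# 23-echo variable-TE multi-echo TSE T2-mapping protocol (7..161 ms step 7)
name: tse_t2map
kind: multiecho_tse
fov: 0.25
matrix_n: 128
n_slices: 1
slice_thickness: 0.006
tr: 4.5
echo_spacing: 0.007
te_list: [0.007, 0.014, 0.021, 0.028, 0.035, 0.042, 0.049, 0.056, 0.063,
          0.070, 0.077, 0.084, 0.091, 0.098, 0.105, 0.112, 0.119, 0.126,
          0.133, 0.140, 0.147, 0.154, 0.161]
flip_excitation_deg: 90
flip_refocus_deg: 180
quantitative: true
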