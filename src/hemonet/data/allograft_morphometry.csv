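cell_line,mouse,mean_length_um,mean_diameter_um
MC38,1,123.9,29.3
MC38,2,129.9,33.0
MC38,3,143,45.5
MC38,4,112.4,23.9
MC38,5,132.1,28.9
MC38,6,130.0,37.5
B16F10,1,123.2,33.9
B16F10,2,123.5,34.1
B16F10,3,131.0,41.6
LLC,1,108.8,35.7
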