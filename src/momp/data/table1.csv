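cell_line,BCL2,MCL1,BAK,BAX,BCLXL
HCC1143,0.907,0.330,3.173,0.638,0.317
MDA-MB-468,1.609,0.051,1.518,0.761,0.416
MDA-MB-231,2.501,0.001,2.202,0.508,1.273
BT20,0.178,0.063,2.764,0.654,0.469
HDQ-P1,4.581,0.059,2.982,1.209,1.175
CAL-85-1,0.061,0.311,1.907,0.987,1.150
BT549,0.619,0.663,0.842,2.284,1.415
HCC1937,0.407,0.078,1.651,0.484,0.557
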