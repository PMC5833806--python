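# Selective BCL-2 family antagonists used for in-silico dose scans.
# kd_nM values are the published binding affinities of each compound for its
# target (discovery-paper values); they are defaults for exploration, not an
# authoritative transcription -- override per run as needed.
# bioavailability_factor 0.5 accounts for drug degradation and active efflux.
antagonists:
  - name: ABT199
    target: BCL2
    kd_nM: 0.01
    bioavailability_factor: 0.5
  - name: WEHI539
    target: BCLXL
    kd_nM: 1.1
    bioavailability_factor: 0.5
  - name: A1210477
    target: MCL1
    kd_nM: 0.45
    bioavailability_factor: 0.5
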