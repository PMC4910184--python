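# Single-HSC repopulation under the reference conditions: one stem cell
# at the center of an empty 31x31 bounded marrow, 500 synchronous steps.
psi: 7
theta: 2
phi: 3
delta: 100
m: 3
eta: 2
width: 31
height: 31
topology: bounded
scenario:
  kind: single_center_stem
steps: 500
snapshot_every: 0
output_dir: out
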