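# Demo: simulate a 4-community study and run the full analysis.
out_dir: demo_out
seed: 7
simulate:
  n_communities: 4
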