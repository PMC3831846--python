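# Toy end-to-end run: simulate a Tb8 master-gene expansion with two
# planted nested subfamily events, then rediscover, track, and date them.
#   alutrack run-all --config examples/toy_sim.yaml --out toy_out
seed: 11
outdir: toy_out
founder: Tb8
simulate:
  timeline_my: 2.0
  non_cpg_rate: 0.0015
  master_copy_rate: 40.0
  stealth_activation_prob: 0.05
  stealth_copy_rate: 4.0
  genome_length: 150000
  truncation_prob: 0.1
  events:
    - {time_my: 0.5, subfamily: TbA, target: "latest:Tb8", edit: Tb8a1_108G_T, copy_rate: 30.0}
    - {time_my: 1.2, subfamily: TbB, target: "latest:TbA", edit: Tb11_42insT, copy_rate: 25.0}
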