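# Synthetic stand-in for the observed E1b1a haplogroup phylogeny (8 Y chromosomes, branch lengths = SNP counts).
# Drawn from starcoal's coalescent simulator under the E1b1a regime model (start_n=40, end_n=2000, t_end=2000 y, duration=12000 y; seq_len=8.8e6 nt, mu=3e-8, 30 y/generation), replicate seed 683, selected on tree structure only.
# Empirical TMRCA from mean root-to-tip SNP count: 14389 years.
# Regenerate with: python scripts/make_fixtures.py
((E_1:88.0,(E_2:70.0,E_3:72.0):7.0,(E_4:31.0,E_5:37.0):48.0):46.0,((E_6:35.0,E_7:54.0):8.0,E_8:51.0):73.0);
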