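# Synthetic stand-in for the observed R1b haplogroup phylogeny (6 Y chromosomes, branch lengths = SNP counts).
# Drawn from starcoal's coalescent simulator under the R1b regime model (start_n=2, end_n=9500, t_end=12000 y, duration=325 y; seq_len=8.8e6 nt, mu=3e-8, 30 y/generation), replicate seed 1184, selected on tree structure only.
# Empirical TMRCA from mean root-to-tip SNP count: 12330 years.
# Regenerate with: python scripts/make_fixtures.py
((R1b_1:109.0,R1b_2:101.0,R1b_3:104.0):1.0,R1b_4:90.0,R1b_5:105.0,R1b_6:139.0);
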