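chrom	start	end	n_probes	seg_mean
1	0	65000	5	0.25
1	65000	91000	2	0.5
1	91000	221000	10	-0.21
2	0	1300000	100	0.0
2	1300000	1365000	5	-0.5
3	0	130000	10	0.3
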