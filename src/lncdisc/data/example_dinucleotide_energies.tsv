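# Illustrative SYNTHETIC dinucleotide physicochemical energy table (kcal/mol).
# Values are generated, not measured; supply your own table for real analyses.
kmer	solvation	stacking	hbond
AA	-6.7104	-9.2457	-12.8914
AC	-9.1773	-11.5072	-15.1831
AG	-8.8121	-11.1758	-14.7431
AT	-6.7926	-9.0792	-12.8531
CA	-9.0731	-11.3989	-14.9377
CC	-10.9811	-13.3226	-17.1635
CG	-11.2364	-13.6792	-16.9965
CT	-8.8063	-11.4587	-15.2884
GA	-9.1327	-11.7730	-15.3337
GC	-10.8306	-13.3689	-16.9358
GG	-10.7694	-14.3082	-17.4437
GT	-9.0108	-11.6939	-14.8115
TA	-6.6615	-8.6478	-12.9869
TC	-9.0790	-11.1204	-15.2566
TG	-9.2710	-11.8185	-14.8597
TT	-6.9105	-9.2660	-13.1507
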