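# Illustrative SYNTHETIC trinucleotide physicochemical energy table (kcal/mol).
# Values are generated, not measured; supply your own table for real analyses.
kmer	solvation	stacking	hbond
AAA	-4.5335	-8.3866	-11.1187
AAC	-7.3362	-9.4322	-14.1960
AAG	-8.1104	-8.9304	-13.1626
AAT	-6.3509	-10.0386	-12.1833
ACA	-8.2021	-11.2200	-13.5196
ACC	-11.0693	-11.9547	-16.2185
ACG	-10.5285	-13.2174	-16.0408
ACT	-7.7065	-11.1740	-14.3565
AGA	-7.5492	-9.3534	-14.1367
AGC	-10.4522	-11.7384	-15.8079
AGG	-9.5385	-12.5200	-16.1594
AGT	-7.5612	-10.3973	-13.5571
ATA	-4.3276	-6.8729	-11.3166
ATC	-9.1627	-10.4461	-13.5956
ATG	-7.6687	-10.5579	-14.3229
ATT	-6.0429	-7.4844	-11.8222
CAA	-8.1430	-10.1924	-14.4893
CAC	-9.8186	-12.3304	-16.0814
CAG	-9.2521	-13.0051	-15.2415
CAT	-7.6456	-9.2975	-14.2762
CCA	-10.7076	-12.4712	-16.5295
CCC	-11.9635	-13.9629	-18.4354
CCG	-12.5179	-14.7895	-17.3048
CCT	-9.3195	-11.8366	-15.4951
CGA	-10.3108	-12.1785	-16.0093
CGC	-12.9988	-15.2815	-17.9342
CGG	-11.8939	-15.5315	-18.8707
CGT	-10.7114	-12.5497	-15.3565
CTA	-8.0671	-10.1522	-14.7666
CTC	-10.1246	-12.7919	-16.2541
CTG	-10.3145	-12.7078	-16.3624
CTT	-8.1566	-11.8000	-14.3083
GAA	-8.6218	-10.6795	-14.9068
GAC	-10.3111	-12.7958	-16.1121
GAG	-9.8690	-13.4155	-16.4674
GAT	-7.5414	-10.7657	-13.8698
GCA	-10.6129	-11.8711	-15.9337
GCC	-10.6715	-15.0348	-17.4373
GCG	-11.3220	-14.8214	-17.9988
GCT	-9.3694	-12.2382	-15.7622
GGA	-10.0100	-13.6929	-16.7152
GGC	-11.3295	-14.3526	-18.6322
GGG	-11.4447	-16.7148	-18.6888
GGT	-9.5533	-12.6456	-16.6944
GTA	-6.7839	-10.8012	-14.1637
GTC	-10.3901	-12.7082	-15.9543
GTG	-11.2771	-13.1970	-15.2983
GTT	-7.8496	-11.3533	-14.0238
TAA	-6.0537	-7.9190	-11.9562
TAC	-8.4458	-9.9335	-14.9400
TAG	-8.1639	-10.0460	-13.4121
TAT	-5.6005	-7.1708	-11.4383
TCA	-8.2026	-10.8038	-13.4307
TCC	-9.6359	-12.5679	-17.4521
TCG	-9.6083	-11.0644	-16.4567
TCT	-7.3924	-8.9694	-15.0017
TGA	-8.8486	-11.3030	-14.4524
TGC	-9.8888	-11.6135	-15.9804
TGG	-10.9405	-12.2935	-15.1004
TGT	-7.9595	-9.8991	-13.4439
TTA	-5.8491	-6.2870	-11.9014
TTC	-8.1155	-9.6118	-13.9077
TTG	-7.2700	-12.9758	-13.9169
TTT	-6.0000	-7.3081	-12.6626
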