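residue	f1	f2	f3	f4	f5	f6	f7	f8	f9	f10
A	-0.0708	-0.0363	2.042	0.0833	-0.6909	-0.1595	0.8089	0.247	0.8653	-0.6856
C	-0.6101	0.9304	-0.8598	-2.2704	-1.5877	2.0066	0.3031	1.2544	-0.2832	1.2844
D	1.3215	-0.2406	-0.0328	-0.3786	-1.2051	-1.0001	-2.1827	0.1921	-0.6053	-0.3764
E	0.8771	-1.4905	1.0755	0.3594	-1.567	-0.4136	-1.0944	0.7263	-0.7496	-0.0389
F	-1.3557	0.1034	-0.4309	0.4127	0.0834	-0.8378	-0.0954	-0.6522	-0.3119	-0.4329
G	1.0818	2.1561	0.7708	-0.9275	1.0748	-1.7997	1.3708	1.279	-1.2098	-0.4607
H	0.0502	-0.6925	-0.884	-0.646	-0.2462	-0.1049	1.1317	-2.3661	-0.8992	-0.4639
I	-1.4829	0.4643	0.5019	0.5572	0.5154	0.2991	-0.9724	-0.1579	-0.9825	0.5435
K	0.8534	-1.529	0.2775	0.3299	1.1786	0.1663	1.0459	0.4462	0.4103	2.5318
L	-1.2857	-0.0395	1.5378	0.8797	0.2142	-0.4039	0.2043	-0.1435	0.6102	1.1927
M	-1.137	-0.6439	0.1372	-0.2988	-1.2288	-0.2498	1.6427	-0.7587	-0.549	-1.0571
N	1.084	0.176	-0.4706	-0.9225	0.3295	-0.7428	-0.3455	-1.4605	0.2522	1.2107
P	1.1823	1.6911	-1.1331	3.073	-1.1942	0.9343	0.7298	-0.0424	-0.1926	0.216
Q	0.5775	-0.9745	-0.0775	-0.0033	-0.1718	0.5254	0.2736	-0.1366	0.2057	0.0131
R	0.6225	-1.545	-0.6197	0.1906	1.7485	1.3909	0.4753	1.3938	-0.8456	-1.7344
S	0.8641	0.7715	0.3854	-0.5939	0.5331	0.4759	-0.3197	-0.8972	1.8029	-0.2643
T	0.3303	0.5745	0.1865	-0.2894	0.6268	1.0737	-0.8036	-0.5953	1.8786	-1.3971
V	-1.1675	0.6155	0.9541	0.1166	0.7447	1.1482	-1.1309	0.1208	-0.7717	-0.186
W	-1.1881	-0.4379	-1.7915	0.138	-0.4309	-1.6467	0.1199	1.7369	2.0818	-0.3312
Y	-0.5467	0.1468	-1.5688	0.19	1.2736	-0.6616	-1.1614	-0.1861	-0.7065	0.4363
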