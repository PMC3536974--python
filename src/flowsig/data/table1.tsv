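gene	rat_p	rat_fc	same_direction	asap_p	asap_fc	flow_annotation	is_query
ZFP36L1	7.80e-07	-1.24	1	0.0101	-1.64	X*4	0
ZFP36	1.08e-05	-1.37	1	2.22e-05	-1.25	X*4	0
FLI1	6.60e-05	1.21	0	3.66e-06	-1.39	X	0
EGR1	7.98e-05	-1.42	1	0.000777	-1.31	X	0
IER2	0.00012	-1.19	1	0.000429	-1.17	X*4	0
SLC2A3	0.00019	1.36	0	6.51e-08	-1.44	X*4	0
FOSB	0.00031	-1.51	1	1.23e-05	-1.42	X	0
TIMP1	0.00045	1.19	0	0.00329	-1.17	X	0
GRK5	0.00053	1.19	1	8.30e-05	1.17	X	0
CCL2	0.00093	-1.47	1	1.32e-06	-1.80	X	0
NID1	0.00098	-1.14	1	0.00197	-1.40	X	0
ITGA5	0.00115	-1.19	1	9.00e-04	-1.74	X	0
SOCS3	0.00119	-1.26	1	2.84e-07	-1.35	X	0
FOS	0.00139	-1.34	1	6.31e-05	-1.65	X	0
KLF2	0.00207	-1.29	1	0.0105	-1.10	X	1
BTG2	0.00314	-1.15	1	1.35e-05	-1.30	X	0
SGK1	0.01066	1.10	0	0.000461	-1.33	X	0
PLEKHO2	0.01227	1.10	0	6.75e-08	-1.25	?	0
PTGER4	0.01418	-1.29	1	1.92e-06	-1.33	X	0
COL6A3	0.01504	1.10	0	9.00e-05	-1.24	X	0
FERMT2	0.02228	1.10	1	0.000179	1.17	?	0
IL1R1	0.03103	NA	NA	0.0104	-1.21	X	0
PKD2	0.04592	NA	NA	7.03e-07	1.30	X	1
GEM	0.13107	NA	NA	0.000193	1.20	X	0
DAB2	0.13354	NA	NA	0.000298	-1.30	X*2	0
GPR116	0.18922	NA	NA	1.99e-08	-1.86	X*2	0
DUSP5	0.27924	NA	NA	8.17e-05	-1.16	X	0
CEBPB	0.40525	NA	NA	0.000551	-1.12	?	0
KLF4	0.44656	NA	NA	8.29e-05	-1.25	X	1
SH2B3	0.48533	NA	NA	8.03e-07	-1.18	?	0
JUNB	0.49141	NA	NA	2.60e-05	-1.40	X	0
CDH5	0.53465	NA	NA	2.52e-05	-1.23	X	0
CD93	0.68071	NA	NA	0.000794	-1.22	X*2	0
CDKN1A	0.71809	NA	NA	0.002	-1.16	X	0
PTPRE	0.79921	NA	NA	4.96e-07	-1.22	X	0
CALD1	0.93732	NA	NA	0.00108	1.17	X*2	0
ERG	0.96645	NA	NA	0.00718	1.14	X*2	0
ELTD1	0.99016	NA	NA	3.03e-05	-1.52	X*4	0
ENG	NA	NA	NA	0.000117	-1.42	X	0
PECAM1	NA	NA	NA	0.000899	-1.48	X	0
CEBPD	NA	NA	NA	0.000296	-1.20	X*4	0
THBS1	NA	NA	NA	0.00201	-1.37	X	0
KIAA0247	NA	NA	NA	5.25e-05	-1.17	?	0
IL4R	NA	NA	NA	1.23e-06	-1.34	X	0
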