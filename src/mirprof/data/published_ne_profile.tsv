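miRNA	NE_R	NE_P
hsa-mir-7641-2-p5	2334.57	657.07
oar-miR-22-3p_R+1	72245.41	23822.97
hsa-miR-34c-5p	2777.84	1090.26
hsa-miR-34a-5p	2522.03	830.34
hsa-miR-141-3p_R-1	28337.35	5791.48
hsa-miR-449a	1842.72	16.28
hsa-mir-7641-2-p3_1ss22TC	3564.20	929.19
bta-miR-31_R+2	3547.01	1305.99
hsa-miR-141-3p_R+1	1673.33	252.36
cgr-miR-142-5p_L-2R+1	5689.25	2523.59
bta-miR-182	3518.63	241.89
cgr-miR-200c	1555.52	316.32
ptr-miR-203_L-1R+1	1896.90	230.26
bta-miR-204	2120.46	608.22
hsa-miR-204-5p	2116.17	607.06
bta-miR-339a_R+1	1836.27	736.73
cfa-miR-375	882.24	89.55
mmu-miR-6240_R-8_1ss1CA	1583.04	381.45
PC-5p-2673_284	3335.48	1146.67
hsa-miR-200a-5p	450.58	39.54
hsa-miR-187-3p_R+1	338.79	12.79
hsa-miR-17-5p	619.97	293.06
cgr-miR-142-3p_L+1R+1	423.49	185.49
hsa-mir-7641-2-p3_1ss1TC	311.28	81.41
bta-miR-6529	281.18	69.78
hsa-miR-190a-5p_R+1	335.35	133.74
bta-miR-183_L-1	153.92	3.49
PC-5p-5933_158	164.24	13.96
PC-5p-6424_145	196.05	37.21
bta-miR-132	271.72	117.46
bta-miR-15b	274.30	125.02
hsa-miR-4792_L+1R+1_1ss10GT	146.18	23.26
hsa-miR-31-3p_R+1	188.31	73.27
hsa-miR-4454_L+1_1ss3GA	122.96	20.93
bta-miR-210_L-1R+1	156.50	53.50
mmu-miR-22-5p_R-1	116.08	22.10
PC-5p-20799_45	75.67	2.33
mmu-miR-3963_R+2_1ss1TC	102.33	19.77
hsa-miR-132-5p	93.73	13.96
hsa-miR-184	72.23	2.33
rno-miR-147_R-1	106.63	25.58
oar-miR-758-3p_R+2	106.63	29.07
cgr-miR-32-5p	109.20	32.56
bta-miR-2478_L+2	98.89	24.42
hsa-miR-24-1-5p_L+1_3ss17TA19TC20-A	108.34	43.03
oan-miR-1386_L+4	87.71	32.56
oan-miR-429-3p_R+2	49.87	3.49
hsa-miR-9-3p_L-1R+1	63.63	14.54
ggo-miR-203b	63.63	20.93
PC-5p-35677_26	53.31	11.63
PC-3p-25064_36	36.11	1.16
PC-5p-10782_91	65.35	25.58
PC-5p-26648_38	45.57	9.30
PC-3p-16127_59	45.57	12.79
hsa-miR-153-3p	54.17	25.58
bta-miR-96	31.82	4.65
hsa-miR-26b-3p	44.71	17.44
mmu-miR-3968_1ss14AT	25.80	3.49
hsa-miR-34c-3p	32.68	9.30
PC-3p-36269_24	24.08	2.33
hsa-miR-21-5p_R+2_1ss4CN	22.36	2.33
mmu-miR-503-5p	26.66	5.81
bta-miR-2285f_L+1R-1	25.80	6.98
bta-miR-6123_R+1	28.38	9.30
ppy-miR-1260b_R+2_1ss9AG	32.68	16.28
bta-miR-212	17.20	2.33
hsa-miR-212-5p	17.20	2.33
hsa-miR-212-3p	19.78	5.81
cgr-miR-32-3p	18.06	4.65
hsa-miR-340-3p_R+1	17.63	4.65
bta-miR-340	17.63	4.65
bta-miR-2427_L+1R-1	13.76	2.33
hsa-miR-190a-3p_L+1	15.48	3.49
oar-miR-154b-3p_L-1	12.04	1.16
bta-miR-545-3p_L-1R+1	21.50	10.47
hsa-miR-141-5p_1ss11TC	11.18	1.16
hsa-miR-491-3p	13.33	3.49
PC-3p-61660_13	17.20	8.14
PC-3p-99692_7	11.18	2.33
PC-5p-91245_7	9.46	1.16
PC-5p-60249_14	10.32	2.33
PC-3p-215602_2	7.74	1.16
PC-3p-82208_8	7.74	1.16
bta-mir-2285o-3-p5_1ss12TC	9.46	2.33
hsa-miR-139-3p	8.60	2.33
cgr-miR-139-3p	8.60	2.33
bta-miR-2284ab	12.04	5.81
PC-5p-108241_6	6.88	1.16
mdo-miR-22-3p_R+1	7.74	2.33
hsa-miR-185-3p_L+1R-1_1ss22TC	7.74	2.33
eca-miR-219-5p_R+2	9.03	4.07
hsa-miR-26a-1-3p_1ss9TC	7.74	3.49
hsa-miR-122-5p_R-1	7.74	3.49
PC-5p-139329_4	7.74	3.49
bta-miR-2284d_L-1R+1_1ss10GA	6.02	0.58
bta-mir-2284z-4-p5_1ss1AG	9.46	4.65
bta-mir-2887-2-p5_1ss7AC	6.02	2.33
bta-miR-677_R+1	6.02	2.33
hsa-miR-153-5p_L+1_2ss15G-16TC	5.16	1.16
bta-miR-2285r_R-2	5.16	1.16
hsa-miR-628-3p_L+1	4.73	0.58
hsa-miR-138-5p	4.73	2.33
hsa-miR-4791_1ss17AT	4.73	2.33
hsa-miR-377-3p	4.30	1.16
ssc-miR-671-5p	4.30	1.16
bta-miR-671_R+1	4.30	1.16
PC-5p-203577_2	4.30	1.16
PC-5p-94605_6	4.30	1.16
PC-3p-247920_2	4.30	1.16
PC-5p-125235_4	4.30	1.16
oar-miR-10a_R+1_1ss12TA	153958.53	657181.33
oar-miR-10b_L+1R-1	160641.52	718168.02
oar-miR-26b_R+1	59229.84	124009.11
oar-miR-26a	142846.73	330581.63
cgr-miR-101b-3p_1ss22GT	8689.09	43584.93
aja-miR-143_1ss22GT	289634.30	1866274.04
oar-miR-133_L+1	144.89	3558.04
cfa-miR-145	2123.04	11338.73
bta-miR-490_R+1	103.19	1465.31
bta-miR-335_R-1	143.60	1430.42
cfa-miR-196b	2885.76	5979.87
mdo-miR-181b-5p	3169.52	7213.76
oar-miR-181a	20920.02	55420.24
hsa-miR-181c-5p_R+1	4420.64	10611.89
hsa-miR-192-5p	2454.10	5510.04
hsa-miR-28-3p_1ss11TA	972.52	3577.22
oar-miR-133_L+1R-2	0.43	64.54
ptr-miR-92_R+2	1121.86	2665.86
hsa-miR-100-5p	416.18	915.24
hsa-miR-767-5p_R-3	2.58	56.98
hsa-miR-490-5p	10.32	93.04
bta-miR-320a	2877.59	9040.17
hsa-miR-299-3p_1ss10TC	141.88	297.71
hsa-miR-133a-5p	0.43	19.77
hsa-miR-335-3p	42.99	198.86
hsa-miR-1_1ss1TC	0.43	20.93
age-miR-19a_1ss23AT	90.29	190.72
hsa-miR-574-5p_R-2	166.67	386.68
hsa-miR-374a-3p_R-1_1ss9AG	164.24	382.61
hsa-miR-143-5p_1ss22TA	238.19	576.82
mdo-miR-599-5p_R-2_1ss9TG	0.86	20.93
hsa-miR-499a-5p	63.63	130.25
bta-mir-2285m-3-p5_1ss1AG	53.74	108.15
bta-miR-216a_R-2	0	18.61
bta-miR-431_R-3	12.90	0
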