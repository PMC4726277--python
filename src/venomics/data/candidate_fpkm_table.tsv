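gene	vg_fpkm	carcass_fpkm	printed_log2	section	description
comp40292_c0	64.12	24.91	1.36	enzymes	PREDICTED: chymotrypsin-1 [Nasonia vitripennis]
comp44498_c3	224.81	22.34	3.33	enzymes	serine protease 22 precursor [Nasonia vitripennis]
comp36113_c0	2008.26	2.67	9.56	enzymes	serine protease 33 precursor [Nasonia vitripennis]
comp29468_c0	1131.96	4.01	8.14	enzymes	serine protease 73 precursor [Nasonia vitripennis]
comp43143_c1	12010.35	34.87	8.43	enzymes	serine protease 87 precursor [Nasonia vitripennis]
comp43143_c3	320.51	1.59	7.66	enzymes	serine protease 87 precursor [Nasonia vitripennis]
comp44055_c7	7795.75	14.18	9.10	enzymes	serine protease homolog 29 precursor [Nasonia vitripennis]
comp36103_c0	3127.21	4.39	9.48	enzymes	serine protease precursor [Nasonia vitripennis]
comp40194_c0	353.14	0.62	9.16	enzymes	PREDICTED: blastula protease 10-like [Nasonia vitripennis]
comp29111_c0	373.03	2.54	7.20	enzymes	PREDICTED: A disintegrin and metalloproteinase with thrombospondin motifs 16-like [Nasonia vitripennis]
comp41685_c0	496.71	0.43	10.16	enzymes	PREDICTED: hypothetical protein LOC100123135 [Nasonia vitripennis]/region_name="ZnMc"
comp6391_c0	11.58	0.00	inf	enzymes	PREDICTED: hypothetical protein LOC100123845 [Nasonia vitripennis]/region_name="ZnMc"
comp44819_c3	1303.00	1.42	9.84	enzymes	lipase A-like precursor [Nasonia vitripennis]
comp28596_c0	1443.05	2.93	8.95	enzymes	lipase-like venom protein precursor [Nasonia vitripennis]
comp41786_c2	671.63	2.61	8.01	enzymes	lipase-like venom protein precursor [Nasonia vitripennis]
comp42555_c0	259.37	0.58	8.81	enzymes	PREDICTED: lipase member H-like [Nasonia vitripennis]
comp45112_c0	3395.22	6.89	8.94	enzymes	PREDICTED: pancreatic lipase-related protein 2-like [Nasonia vitripennis]
comp28462_c0	1339.53	3.39	8.63	enzymes	PREDICTED: pancreatic lipase-related protein 2-like [Nasonia vitripennis]
comp22275_c0	209.17	0.48	8.78	enzymes	PREDICTED: pancreatic lipase-related protein 2-like [Nasonia vitripennis]
comp36060_c0	1523.36	1.18	10.34	enzymes	PREDICTED: pancreatic triacylglycerol lipase-like [Nasonia vitripennis]
comp22302_c0	2085.48	2.72	9.58	enzymes	PREDICTED: hypothetical protein LOC100122136 [Nasonia vitripennis]/region_name="Abhydro_lipase"
comp44469_c0	87.90	16.55	2.41	enzymes	PREDICTED: esterase E4 [Nasonia vitripennis]
comp43397_c2	588.20	1.07	9.10	enzymes	PREDICTED: venom acid phosphatase Acph-1-like [Nasonia vitripennis]
comp23069_c0	1158.10	6.40	7.50	enzymes	PREDICTED: venom acid phosphatase Acph-1-like isoform 1 [Nasonia vitripennis]
comp36032_c0	7780.99	16.12	8.91	enzymes	venom acid phosphatase [Pteromalus puparum]
comp43694_c1	11.98	0.13	6.57	enzymes	PREDICTED: ribonuclease 1-like [Nasonia vitripennis]
comp28533_c0	1882.32	56.40	5.06	enzymes	inosine-uridine preferring nucleoside hydrolase-like precursor [Nasonia vitripennis]
comp42418_c0	3923.13	7.94	8.95	enzymes	endonuclease-like venom protein precursor [Nasonia vitripennis]
comp45389_c0	210.31	0.40	9.05	enzymes	PREDICTED: adenosine deaminase CECR1-like [Nasonia vitripennis]
comp28685_c0	155.45	25.07	2.63	enzymes	glucosamine (N-acetyl)-6-sulfatase precursor [Nasonia vitripennis]
comp22216_c0	6576.38	5.64	10.19	enzymes	PREDICTED: alpha-amylase 1-like [Nasonia vitripennis]
comp41097_c0	28.35	3.22	3.14	enzymes	PREDICTED: glucose dehydrogenase [acceptor]-like [Nasonia vitripennis]
comp45178_c0	607.76	0.77	9.62	enzymes	PREDICTED: gamma-glutamyltranspeptidase 1 [Nasonia vitripennis]
comp36384_c0	1065.20	92.54	3.52	enzymes	PREDICTED: gamma-interferon-inducible lysosomal thiol reductase-like [Nasonia vitripennis]
comp39547_c0	1377.55	6.52	7.72	enzymes	PREDICTED: kynurenine-oxoglutarate transaminase 1-like [Nasonia vitripennis]
comp36135_c0	1720.14	2.56	9.39	enzymes	PREDICTED: kynurenine-oxoglutarate transaminase 3-like [Megachile rotundata]
comp29610_c1	24.30	0.00	inf	enzymes	PREDICTED: kynurenine-oxoglutarate transaminase 3-like [Nasonia vitripennis]
comp22192_c0	534.83	252.92	1.08	enzymes	PREDICTED: protein disulfide-isomerase A3-like [Nasonia vitripennis]
comp22195_c0	11118.41	33.42	8.38	protease_inhibitors	PREDICTED: hypothetical protein LOC100677882 [Nasonia vitripennis]/region_name="KAZAL_FS"
comp36018_c0	21799.59	571.10	5.25	protease_inhibitors	PREDICTED: hypothetical protein LOC100680056 [Nasonia vitripennis]/region_name="KAZAL_FS"
comp44498_c8	449.23	74.76	2.59	protease_inhibitors	PREDICTED: hypothetical protein LOC100117405 [Nasonia vitripennis]/region_name="Pacifastin_I"
comp43457_c1	214.00	105.07	1.03	protease_inhibitors	PREDICTED: hypothetical protein LOC100118367 [Nasonia vitripennis]/region_name="SERPIN"
comp39522_c0	11298.69	38.03	8.21	recognition_binding	GOBP-like venom protein precursor [Nasonia vitripennis]
comp36458_c0	222.54	0.19	10.22	recognition_binding	PREDICTED: beta-1,3-glucan-binding protein [Nasonia vitripennis]
comp44465_c2	177.85	0.17	10.01	recognition_binding	low-density lipoprotein receptor-like venom protein precursor [Nasonia vitripennis]
comp39967_c0	13.21	3.29	2.00	recognition_binding	PREDICTED: low-density lipoprotein receptor-related protein 2-like [Nasonia vitripennis]
comp22191_c0	590.17	217.32	1.44	others	calreticulin [Pteromalus puparum]
comp45101_c0	9683.63	9.36	10.01	others	PREDICTED: venom allergen 3-like isoform 1 [Nasonia vitripennis]
comp40314_c0	22.65	9.07	1.32	others	major royal jelly protein-like 7 precursor [Nasonia vitripennis]
comp41377_c0	4040.63	3.25	10.28	others	major royal jelly protein-like 9 precursor [Nasonia vitripennis]
comp42400_c0	959.54	134.66	2.83	others	PREDICTED: protein FAM151A-like [Nasonia vitripennis]
comp42334_c0	84.05	14.01	2.58	others	PREDICTED: protein lethal(2)essential for life-like [Nasonia vitripennis]
comp43276_c5	596.79	0.70	9.74	others	venom protein A1YI24CM3 [Chelonus inanitus]
comp22190_c0	1507.25	3.23	8.87	unknown	venom protein D precursor [Nasonia vitripennis]
comp45096_c0	12371.95	110.95	6.80	unknown	venom protein G precursor [Nasonia vitripennis]
comp36121_c0	1880.93	2.15	9.77	unknown	venom protein J precursor [Nasonia vitripennis]
comp39496_c0	3197.36	6.01	9.05	unknown	venom protein K precursor [Nasonia vitripennis]
comp22199_c0	14424.76	30.52	8.88	unknown	venom protein L precursor [Nasonia vitripennis]
comp39484_c0	951.21	2.35	8.66	unknown	venom protein O precursor [Nasonia vitripennis]
comp22466_c0	2360.55	4.93	8.90	unknown	venom protein U precursor [Nasonia vitripennis]
comp45164_c0	4856.06	5.48	9.79	unknown	venom protein Z precursor [Nasonia vitripennis]
comp28217_c0	3818.61	4.69	9.67	unknown	PREDICTED: hypothetical protein LOC100117668 [Nasonia vitripennis]
comp39512_c0	4969.28	8.03	9.27	unknown	PREDICTED: hypothetical protein LOC100119874 [Nasonia vitripennis]
comp22365_c0	1440.42	2.91	8.95	unknown	PREDICTED: hypothetical protein LOC100122343 [Nasonia vitripennis]
comp44303_c0	5418.77	4.69	10.17	unknown	PREDICTED: hypothetical protein LOC100122910 [Nasonia vitripennis]
comp22193_c0	1795.35	13.76	7.03	unknown	PREDICTED: hypothetical protein LOC100678001 isoform 1 [Nasonia vitripennis]
comp37024_c0	3026.09	5.75	9.04	unknown	PREDICTED: hypothetical protein LOC100678044 [Nasonia vitripennis]
comp22198_c0	2164.89	3.08	9.46	unknown	PREDICTED: hypothetical protein LOC100678968 [Nasonia vitripennis]
comp28774_c0	1248.40	1.84	9.41	unknown	PREDICTED: hypothetical protein LOC100679301 [Nasonia vitripennis]
comp41010_c0	103.99	0.86	6.92	unknown	PREDICTED: hypothetical protein LOC100679659 isoform 1 [Nasonia vitripennis]
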