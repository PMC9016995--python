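species	accession	clade	length_bp	lsc_bp	ir_bp	ssc_bp	gc_total	gc_lsc	gc_ir	gc_ssc
B. disciflorum	LC498826	AN	148554	79001	26378	16797	37.94	35.80	43.38	30.93
B. gedangense	MW161053	AN	158524	86200	26846	18632	36.76	34.47	43.05	29.26
B. lingii	MW161052	AN	156669	84607	26919	18224	36.77	34.35	43.09	29.30
B. menghaiense	MW161050	AN	156550	84663	26891	18105	36.66	34.20	43.03	29.26
B. pentaneurum	MW161051	AN	156142	84240	26838	18226	36.81	34.44	43.05	29.40
B. pingnanense	MW822749	AN	151224	86017	25855	13497	36.98	34.45	43.21	29.25
B. inconspicuum	NC_046811	AN	149548	85760	25824	12140	37.00	34.41	43.17	29.00
B. forrestii	LC642719	AN	148067	78167	26414	17072	37.91	35.86	43.29	30.63
B. hirtum	LC642724	AN	147382	77587	26333	17129	37.96	35.93	43.34	30.60
B. hirundinis	LC642721	AN	144380	77399	26437	14107	38.02	35.79	43.22	30.76
B. kwangtungense	LC642722	AN	145092	77192	26262	15376	37.98	35.93	43.31	30.03
B. leopardinum	LC642723	AN	147514	77762	26378	16996	38.04	36.05	43.37	30.58
B. odoratissimum	LC642720	AN	147494	77664	26290	17250	37.88	35.87	43.32	30.34
B. orientale	LC642725	AN	147388	77392	26395	17206	38.01	36.05	43.29	30.65
B. reptans	LC642726	AN	146928	77088	26401	17038	37.98	35.98	43.29	30.58
B. andersonii	LC703293	AN	148255	78074	26366	17449	37.83	35.84	43.32	30.19
B. affine	LC556091	AN	148230	78178	26386	17280	37.86	35.83	43.30	30.38
B. pectinatum	LC556092	AN	147169	77478	26081	17529	38.01	36.01	43.37	30.87
B. funingense	LC556093	AN	147464	77564	26403	17094	37.92	35.89	43.25	30.68
B. epiphytum	NC_048486	SA	147546	82354	25847	13498	36.73	34.06	43.20	28.20
B. exaltatum	NC_048480	SA	150410	83335	25847	15381	36.78	34.21	43.22	29.09
B. granulosum	NC_048481	SA	151112	84492	25465	15690	36.72	34.26	43.13	29.13
B. mentosum	NC_048482	SA	150217	83642	26338	13899	36.74	34.14	43.11	28.28
B. plumosum	NC_048479	SA	146401	83260	26025	11091	36.56	33.72	43.00	27.62
B. regnellii	NC_048483	SA	151493	84868	25542	15541	36.66	34.17	43.09	29.11
B. steyermarkii	NC_048484	SA	146720	83488	25953	11326	36.74	34.20	42.80	27.72
B. weddellii	NC_048485	SA	151355	83450	25927	16051	36.64	34.09	43.16	28.90
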