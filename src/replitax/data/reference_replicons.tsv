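strain	replicon	role	size_bp	gc_percent	accession
rho-6.2	Chromosome	chromosome	3709686	60.92	CP117267
rho-6.2	Putative chromid 1	chromid	1530638	58.41	CP117268
rho-6.2	Megaplasmid pTi6.2	megaplasmid	381845	56.14	CP117269
rho-6.2	Putative chromid 2	chromid	336962	60.98	CP117270
1078	Chromosome	chromosome	3664408	60.77	CP117255
1078	Megaplasmid pRt1078	megaplasmid	834411	57.79	CP117256
1078	Megaplasmid pTi1078	megaplasmid	439071	56.21	CP117257
1078	Putative chromid 1	chromid	432998	60.2	CP117258
1078	Putative chromid 2	chromid	304572	61.07	CP117259
1078	Putative chromid 3	chromid	302267	60.24	CP117260
932	Chromosome	chromosome	3816680	60.66	CP117261
932	Megaplasmid pRt932	megaplasmid	756443	58.29	CP117262
932	Megaplasmid pTi932	megaplasmid	430508	56.05	CP117263
932	Putative chromid 1	chromid	339618	60.61	CP117264
932	Putative chromid 2	chromid	319653	60.41	CP117265
932	Putative chromid 3	chromid	304177	61.03	CP117266
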