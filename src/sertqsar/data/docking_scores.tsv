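id	HBond	NoHBond90	Steric	VdW	Energy	MolDock	Rerank	pIC50
A	0	0	-175.949	-42.2977	-153.22	-149.929	-98.698	7.8952
A1	0	-0.69399	-181.955	-22.7734	-157.652	-154.178	-117.876	8.0215
A2	-2.40454	-2.40454	-181.522	20.5607	-159.86	-152.977	-95.0434	7.931
A3	0	-2.5	-203.228	-43.7415	-177.416	-174.068	-139.04	8.1855
A4	-2.19821	-2.5	-182.575	-41.1272	-173.611	-164.111	-121.914	8.007
A5	-1.09053	-6.1829	-181.313	25.7723	-158.802	-156.679	-89.5642	7.6785
A6	0	0	-189.35	-50.3446	-171.667	-169.208	-138.993	8.0295
A7	0	-0.20938	-182.255	-48.7535	-163.942	-161.211	-132.397	8.1943
A8	-0.37688	-4.80842	-194.602	28.4043	-176.14	-172.675	-125.456	8.4814
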