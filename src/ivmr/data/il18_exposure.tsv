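variant_id	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue
rs2250417	11	111590526	NA	NA	NA	0.1	0.01	1.9e-32
rs2300702	2	316411522	NA	NA	NA	0.07	0.01	1.6e-17
rs2268797	2	31637256	NA	NA	NA	0.07	0.01	2.8e-17
rs6748621	2	32115705	NA	NA	NA	0.08	0.01	1.1e-16
rs7577696	2	32132286	NA	NA	NA	0.08	0.01	2.7e-19
rs6760105	2	32160890	NA	NA	NA	0.06	0.01	3.6e-16
rs212745	2	32266336	NA	NA	NA	0.07	0.01	2.1e-15
rs212713	2	32311041	NA	NA	NA	0.06	0.01	1.5e-10
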