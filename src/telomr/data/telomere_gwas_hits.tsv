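snp_id	chrom	locus	long_allele	beta_kb	se_kb	p_value	source	excluded_reason
rs10936599	3	TERC	C	0.117		2.5e-31	Codd 2013
rs2736100	5	TERT	C	0.094		4.4e-19	Codd 2013
rs7726159	5	TERT	A	0.073		4.7e-17	Pooley 2013	LD (r2=0.382) with rs2736100 (TERT)
rs7675998	4	NAF1	G	0.090		4.3e-16	Codd 2013
rs9420907	10	OBFC1	C	0.083		6.9e-11	Codd 2013
rs6772228	3	PXK	T	0.120		3.9e-10	Pooley 2013
rs8105767	19	ZNF208	G	0.058		1.1e-09	Codd 2013
rs755017	20	RTEL1	G	0.074		6.7e-09	Codd 2013
rs412658	19	ZNF676	T	0.050		9.8e-09	Mangino 2012	LD (r2=0.704) with rs8105767 (ZNF208)
rs3027234	17	CTC1	C	0.057		2.3e-08	Mangino 2012
rs11125529	2	ACYP2	A	0.067		4.5e-08	Codd 2013
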