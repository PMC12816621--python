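GLYCOLYTIC_14	14-gene glycolytic signature used for PDAC stratification	HK1	HK2	PGAM4	LDHA	SLC2A1	PKM2	ALDOA	ENO1	ALDOC	GPI	PGAM1	GAPDH	TPI1	PKLR
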