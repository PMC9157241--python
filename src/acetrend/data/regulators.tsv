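symbol	role	family	aliases
Kat1	acetyltransferase	KAT	Hat1
Kat2a	acetyltransferase	KAT	GCN5
Kat2b	acetyltransferase	KAT	PCAF
Kat3a	acetyltransferase	KAT	Crebbp
Kat3b	acetyltransferase	KAT	Ep300
Kat5	acetyltransferase	KAT	Tip60
Kat6a	acetyltransferase	KAT	MOZ
Kat6b	acetyltransferase	KAT	MORF
Kat7	acetyltransferase	KAT	HBO1
Kat8	acetyltransferase	KAT	MOF
Atat1	acetyltransferase	KAT
Esco1	acetyltransferase	KAT
Esco2	acetyltransferase	KAT
Hdac1	deacetylase	HDAC
Hdac2	deacetylase	HDAC
Hdac3	deacetylase	HDAC
Hdac4	deacetylase	HDAC
Hdac5	deacetylase	HDAC
Hdac6	deacetylase	HDAC
Hdac7	deacetylase	HDAC
Hdac8	deacetylase	HDAC
Hdac9	deacetylase	HDAC
Hdac10	deacetylase	HDAC
Hdac11	deacetylase	HDAC
Sirt1	deacetylase	SIRT
Sirt2	deacetylase	SIRT
Sirt3	deacetylase	SIRT
Sirt4	deacetylase	SIRT
Sirt5	deacetylase	SIRT
Sirt6	deacetylase	SIRT
Sirt7	deacetylase	SIRT
Lef1	deacetylase	TF_deacetylase
Tcf7	deacetylase	TF_deacetylase	TCF1
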