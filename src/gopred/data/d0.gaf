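!gaf-version: 2.1
UniProtKB	p1	p1		GO:0000004	GO_REF:0000002	EXP		P			protein	taxon:0	20110901	SYN
UniProtKB	p2	p2		GO:0000004	GO_REF:0000002	EXP		P			protein	taxon:0	20110901	SYN
UniProtKB	p2	p2		GO:0000003	GO_REF:0000002	EXP		P			protein	taxon:0	20110901	SYN
UniProtKB	p3	p3		GO:0000005	GO_REF:0000002	EXP		P			protein	taxon:0	20110901	SYN
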