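B-cell differentiation	core function	CR2	CD79A	CD79B	CD22	MS4A1
B-cell activation	core function	CR2	CD79A	CD79B	CD22	MS4A1	PRKCB
B-cell receptor signaling pathway	core function	CR2	CD79A	CD79B	CD22	PRKCB
Neutrophil chemotaxis	core function	SAA1	END2	END3	CCL13	CCL8	CCL26	CCL23	CXCL11	CXCL8	CXCL5	CXCL2	CXCL1	PPBP	CXCL3	CXCL6	PF4	CCL19	TREM1	CCL14
Chemokine activity	core function	CXCL1	CXCL2	CXCL5	CXCL6	CXCL8	CCL19	PF4	CXCL3	PPBP	CCL13	CCL26	CXCL11	CXCL12	CCL14	CCL28	CCL8	CCL23
Chemokine-mediated signaling pathway	core function	CXCL5	CXCL2	CXCL8	CXCL1	CXCL11	CCL26	PF4	CCL14	CCR2	CXCL6	CXCL12	CCL13	PPBP	CCL23	TFF2	CCL8	CCL19	CXCL3
CXCR chemokine receptor binding	core function	CXCL1	CXCL2	CXCL5	CXCL8
Peptidoglycan binding	core function	REG3G	REG3A	ZG16
Negative regulation of keratinocyte differentiation	core function	REG3G	REG3A	MSX2
Oligosaccharide binding	core function	REG3G	REG3A	ITLN1
Positive regulation of keratinocyte proliferation	core function	REG3G	REG3A	AREG	CDH3
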