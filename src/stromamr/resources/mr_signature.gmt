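MESENCHYMAL_MRS	mesenchymal master regulators	AEBP1	HOPX	PRRX1	SNAI2	ZEB1	ZEB2
IMMUNOREACTIVE_MRS	immunoreactive master regulators	BATF	BTN3A3	ETV7	HCLS1	IKZF1	IKZF3	IRF7	IRF9	SP140	TFEC
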