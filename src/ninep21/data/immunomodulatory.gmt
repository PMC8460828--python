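Trafficking	immunomodulatory: immune cell trafficking	CXCL13	CXCL9	XCL2	CCL5	CXCL10
Activation_expansion	immunomodulatory: T-cell activation and clonal expansion	CD27	CD28	ICOS	IL21	IL2	TNFRSF9	TNFRSF4	CD40	CD80	CD86
Suppressive	immunomodulatory: immune suppressive signaling	PVR	TGFB1	NT5E	VEGFA	CD276	IL10	IDO1
Checkpoints	immunomodulatory: inhibitory checkpoints	CD274	CTLA4	PDCD1	LAG3	HAVCR2	TIGIT
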