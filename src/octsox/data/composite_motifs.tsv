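Hoxb1-like	HWTTSWNATGYWDWD
Utf1-like	HWTTSWNATGYWDGD
Fgf4-like	HWTTSWNNNNATGYWDWD
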