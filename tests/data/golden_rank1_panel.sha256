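746bc312fd89ef5cb32ebb868cb512687be4f7258c18e092a83a13d8d3051710
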