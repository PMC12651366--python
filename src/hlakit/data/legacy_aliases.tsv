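# Legacy (pre-April-2010) allele designations that were *renamed* in the
# nomenclature revision, keyed without the HLA- prefix. Purely mechanical
# conversions (adding colons, dropping the Cw "w") are handled by the parser;
# this table holds the exceptions. Unknown legacy names error rather than
# guess. Editable.
legacy	current
CW0702	HLA-C*07:02
CW0401	HLA-C*04:01
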