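((((( Homo_sapiens:6.7, Pan_troglodytes:6.7):2.4, Gorilla_gorilla_gorilla:9.1):6.7, Pongo_abelii:15.8):4.4, Nomascus_siki:20.2):9.2, Macaca_mulatta:29.4);
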