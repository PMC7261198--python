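>H1.0 human linker-histone H1.0 N-terminal domain, 26 aa (UniProt-derived; numbering notes in docs/methods.md)
MTENSTSAPAAKPKRAKASKKSTDHP
>H1.1 human linker-histone H1.1 N-terminal domain, 37 aa (UniProt-derived with K34; numbering notes in docs/methods.md)
MSETVPPAPAASAAPEKPLAGKKAKKPAKAAAAKAKK
>H1.2 human linker-histone H1.2 N-terminal domain, 36 aa (UniProt-derived; numbering notes in docs/methods.md)
MSETAPAAPAAAPPAEKAPVKKKAAKKAGGTPRKAS
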