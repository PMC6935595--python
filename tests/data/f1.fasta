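>copy1
AAAAAAAAAATAAAAAAAAATAAAAAAAAAAATTATAAAA
>copy2
TAAAAAAAAAAAAAAAAAAATAAAAAAAAAAATTAAAAAA
>copy3
AAAAAAAAAATAAAAAAAAATAAAAAAAAAAATTATAAAA
>copy4
AAATATAAAAAAAAAAATAAAAAAAAAATAAAAAAATATA
>copy5
AAAAAAAAAATAAAAAAAAATATAAAAAAAAATTAAAAAA
>copy6
AAATATAAAAAAAAAAATAAAAAAAAAATAAAAAAATATA
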