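% mode=single
@relation golden_toy

@attribute f0 numeric
@attribute f1 numeric
@attribute Y {-1,1}
@attribute I string
@attribute C {1,2,3,4,5,6,7,8,9,10,11,12}
@attribute msg string

@data
1.5,-2.25,1,1,3,'P'
0.125,3,-1,1,7,'P'
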