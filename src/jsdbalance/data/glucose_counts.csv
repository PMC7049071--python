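level,Disadvantaged,Elderly,Reference
<109,7191,3637,64265
109-125,1025,835,7298
>125,1715,685,6932
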