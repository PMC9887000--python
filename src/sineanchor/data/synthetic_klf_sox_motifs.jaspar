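>SYN0001.1 KLF_like_synthetic
A [   3   3   3   3   4   3   3   3   3 ]
C [   3   3   3   3   4   3   3   3   3 ]
G [  91  91  91  91   4  91  91  91  91 ]
T [   3   3   3   3  88   3   3   3   3 ]
>SYN0002.1 SOX_like_synthetic
A [  88   88    4   88   88    4    4 ]
C [   4    4   88    4    4    4    4 ]
G [   4    4    4    4    4    4   88 ]
T [   4    4    4    4    4   88    4 ]
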