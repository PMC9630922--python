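rater,side,condition,fisher_z
A,L,ipsilateral,0.950
A,R,ipsilateral,0.931
B,L,ipsilateral,0.952
B,R,ipsilateral,0.954
C,L,ipsilateral,0.916
C,R,ipsilateral,0.930
D,L,ipsilateral,0.933
D,R,ipsilateral,0.923
E,L,ipsilateral,0.944
E,R,ipsilateral,0.910
F,L,ipsilateral,0.943
F,R,ipsilateral,0.905
G,L,ipsilateral,0.928
G,R,ipsilateral,0.902
H,L,ipsilateral,0.875
H,R,ipsilateral,0.877
A,L,contralateral,0.952
A,R,contralateral,0.924
B,L,contralateral,0.942
B,R,contralateral,0.935
C,L,contralateral,0.902
C,R,contralateral,0.871
D,L,contralateral,0.901
D,R,contralateral,0.863
E,L,contralateral,0.930
E,R,contralateral,0.895
F,L,contralateral,0.907
F,R,contralateral,0.896
G,L,contralateral,0.890
G,R,contralateral,0.839
H,L,contralateral,0.849
H,R,contralateral,0.781
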