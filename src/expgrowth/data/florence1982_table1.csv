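t,Y,N_u,N_c,P_u,P_c,K_u,K_c
19.6,0.406,13,32,1,2.5,18,44.2
21.0,1.83,60,32.8,6,3.3,118,64.5
22.0,4.21,110,26.1,13,3.1,219,52.1
24.0,10.2,171,16.8,22,2.2,298,29.2
26.8,18.8,198,10.5,34,1.6,267,12.5
29.5,22.5,207,9.2,34,1.5,293,13.0
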