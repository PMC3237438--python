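t,x,erf_x,gauss_x,Q,Y
19.6,0,0,1,0,0.406
21.0,0.175,0.1999,0.9698,0.285,1.83
22.0,0.300,0.3286,0.9139,0.571,4.21
24.0,0.550,0.5633,0.7390,1.300,10.2
26.8,0.900,0.7969,0.4449,2.363,18.8
28.8,1.150,0.8961,0.2665,2.965,21.3
29.5,1.2375,0.9198,0.2162,3.131,22.5
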