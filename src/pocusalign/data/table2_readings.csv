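sample,participant,modality,angle_deg,label
0,1,POCUS,3.7,
0,1,X-ray,8.7,
0,2,POCUS,0.0,
0,2,X-ray,3.0,
0,3,POCUS,,
0,3,X-ray,,
1,1,POCUS,,
1,1,X-ray,,
1,2,POCUS,,
1,2,X-ray,,
1,3,POCUS,,
1,3,X-ray,,
2,1,POCUS,,
2,1,X-ray,,
2,2,POCUS,,
2,2,X-ray,,
2,3,POCUS,,
2,3,X-ray,,
3,1,POCUS,21.0,
3,1,X-ray,10.0,
3,2,POCUS,20.0,
3,2,X-ray,8.0,
3,3,POCUS,24.0,
3,3,X-ray,8.0,
4,1,POCUS,7.9,
4,1,X-ray,15.0,
4,2,POCUS,9.0,
4,2,X-ray,8.0,
4,3,POCUS,17.0,
4,3,X-ray,5.0,
5,1,POCUS,9.1,
5,1,X-ray,7.0,
5,2,POCUS,4.0,
5,2,X-ray,2.0,
5,3,POCUS,10.0,
5,3,X-ray,7.0,
6,1,POCUS,3.0,
6,1,X-ray,,
6,2,POCUS,,
6,2,X-ray,,
6,3,POCUS,,
6,3,X-ray,,
7,1,POCUS,4.2,
7,1,X-ray,9.3,
7,2,POCUS,4.0,
7,2,X-ray,4.0,
7,3,POCUS,7.0,
7,3,X-ray,9.0,
8,1,POCUS,,
8,1,X-ray,,
8,2,POCUS,,
8,2,X-ray,,
8,3,POCUS,,
8,3,X-ray,,
9,1,POCUS,5.8,
9,1,X-ray,9.7,
9,2,POCUS,8.0,
9,2,X-ray,10.0,
9,3,POCUS,10.0,
9,3,X-ray,9.0,
10,1,POCUS,4.2,
10,1,X-ray,14.3,
10,2,POCUS,6.0,
10,2,X-ray,8.0,
10,3,POCUS,8.0,
10,3,X-ray,9.0,
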