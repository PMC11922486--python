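#,Avg. invasive CVP (mmHg),Vein,CF (N),HO (cmH2O),CF Pred. CVP (mmHg),Multi-feature Pred. CVP (mmHg),JVP (mmHg),Trained model CVP (mmHg)
1,8.5,LIJ,9.73,2.76,10.14,9.94,-,6.13
2,5.0,LIJ,3.66,5.00,3.78,4.03,3.68,5.25
3,4.5,LIJ,5.31,5.00,5.51,5.76,-,5.94
4,4.0,LIJ,3.18,3.11,3.28,3.38,3.68,4.48
5,5.5,LIJ,5.91,2.58,6.14,5.91,X,4.42
6,0.5,LEJ,2.23,0.00,2.28,1.55,X,0.98
7,10.5,LIJ,8.38,2.58,8.72,8.50,X,5.44
8,9.0,REJ,7.53,4.06,7.83,7.90,-,6.18
9,3.0,LIJ,3.38,5.00,3.49,3.73,3.68,5.14
10,5.5,RIJ,5.70,6.43,5.92,6.44,9.19,6.92
11,3.5,LIJ,2.37,3.43,2.43,2.37,4.41,3.55
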