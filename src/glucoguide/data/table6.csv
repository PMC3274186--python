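time,blood_sugar,systolic,diastolic,exercise,meal,target_calories,treatment
0,0.0199,0.5,0.38,0.48,0,0.752,5
0.111,0.399,0.45,0.3,0,0.294,0.798,1
0.333,0.067,0.7625,0.5,0,0,0.984,2
0.777,0.670,0.8,0.36,0,0,0.35,4
0.111,0,0.5,0.3,0.6,0,0.798,3
0.167,0.225,0.5375,0.26,0.7,0,1,1
0.111,0.0188,0.45,0.28,0,0.544,1,3
1,0.134,0.25,0.68,0,0,0.081,2
0.444,0.391,0.4125,0.66,0,0.516,1,1
0.389,0.139,0.65,0.52,0,0.5,1,5
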