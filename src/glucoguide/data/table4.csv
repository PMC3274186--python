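time,blood_sugar,systolic,diastolic,exercise,meal,target_calories,treatment
5,84,140,69,240,0,"1,267",5
7,199,136,65,0,200,"1,344",1
11,75,161,75,0,0,"1,653",2
19,300,164,68,0,0,600,4
7,50,140,65,300,0,"1,344",3
8,134,143,63,350,0,"2,000",1
7,57,136,64,0,370,"2,439",3
23,100,120,84,0,0,150,2
13,196,133,83,0,351,"2,000",1
12,102,152,76,0,340,"2,000",5
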