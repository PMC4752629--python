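case,baseline_category,detection_round,sex,age,tnm,stage,histology,treatment
1,4,baseline,M,59,pT1a pN0,IA,adenocarcinoma,surgery
2,4,baseline,M,66,pT1a pN0,IA,adenocarcinoma,surgery
3,4,baseline,M,66,pT1a pN0,IA,adenocarcinoma,surgery
4,4,baseline,M,55,pT1b pN0,IA,adenocarcinoma,surgery
5,4,baseline,M,63,pT1a pN0,IA,adenocarcinoma,surgery
6,4,baseline,F,64,pT1a pN0,IA,adenocarcinoma,surgery
7,4,baseline,M,67,pT1b pN0,IA,small cell carcinoma,surgery+chemo
8,4,baseline,M,62,pT1a pN0,IA,squamous cell carcinoma,surgery
9,4,baseline,M,68,pT1b pN0,IA,squamous cell carcinoma,surgery
10,4,baseline,M,67,pT1a pN0,IA,squamous cell carcinoma,surgery
11,4,baseline,M,73,pT1b pN0,IA,squamous cell carcinoma,surgery
12,4,baseline,M,71,pT1a pN0,IA,adenocarcinoma,surgery
13,4,baseline,M,72,cT1b cN0 cM0,IA,adenocarcinoma,radio
14,4,baseline,M,64,pT1b pN0,IA,adenocarcinoma,surgery
15,4,baseline,M,68,pT1a pN0,IA,adenocarcinoma,surgery
16,4,baseline,M,74,cT1a cN0 cM0,IA,bronchogenic carcinoma,palliative
17,4,baseline,M,69,pT1a pN0,IA,squamous cell carcinoma,surgery
18,4,baseline,M,70,pT2a pN0,IB,adenocarcinoma,surgery
19,4,baseline,M,67,pT2a pN0,IB,adenocarcinoma,surgery
20,4,baseline,M,68,pT2a pN1,IIA,squamous cell carcinoma,surgery+chemo
21,4,baseline,F,67,pT1a pN1,IIA,squamous cell carcinoma,surgery+chemo
22,4,baseline,F,64,pT2b pN0,IIA,adenocarcinoma,surgery+chemo
23,4,baseline,F,73,pT2a pN1,IIA,small cell carcinoma,surgery+chemo
24,4,baseline,M,63,pT1a pN1,IIA,adenocarcinoma,surgery+chemo
25,4,baseline,M,75,pT2a pN1,IIA,squamous cell carcinoma,surgery+chemo
26,4,baseline,M,64,pT2b pN0,IIA,carcinoid,surgery
27,4,baseline,M,68,pT1a pN2,IIIA,adenocarcinoma,surgery
28,4,baseline,F,69,pT1b pN2,IIIA,adenocarcinoma,surgery+chemo
29,4,baseline,M,63,cT1a cN2 cM0,IIIA,small cell carcinoma,chemo
30,4,baseline,F,60,pT3 pN0,IIB,squamous cell carcinoma,surgery+radio
31,4,baseline,M,66,cT4 cN3 cM1b,IV,adenocarcinoma,chemo+radio
32,4,baseline,M,64,cT3 cN2 cM1b,IV,squamous cell carcinoma,palliative
33,3,3m,M,68,pT1a pN0,IA,adenocarcinoma,surgery
34,3,12m,M,69,pT1a pN0,IA,adenocarcinoma,surgery
35,3,12m,M,61,pT1a pN0,IA,squamous cell carcinoma,surgery
36,3,12m,M,70,pT1a pN0,IA,adenocarcinoma,surgery
37,3,3m,F,70,pT1a Nx,IA,adenocarcinoma,surgery
38,3,12m,M,66,pT1b pN0,IA,squamous cell carcinoma,surgery
39,3,12m,F,69,cT1a cN0 cM0,IA,adenocarcinoma,radio
40,3,12m,M,71,pT1a pN0,IA,adenocarcinoma,surgery
41,3,12m,F,75,cT4 cN2 cM1b,IV,adenocarcinoma,other
42,2,12m,F,66,pT1a pN0,IA,adenocarcinoma,surgery
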