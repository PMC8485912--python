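participant_id,p_mpg_below,p_mpg_above,p_mage_below,p_mage_above,p_auc24_below,p_auc24_above
1,35.4,4.50,83.2,4.37,0,0
2,17.3,28.6,33.0,43.7,0,0
3,0.567,78.5,43.4,21.7,0,0.133
4,22.7,37.2,91.6,4.47,0,0
5,2.73,63.7,1.70,94.0,0.133,0
6,0.367,87.9,12.6,66.5,0,0
7,0,99.2,9.87,55.5,0,44.8
8,81.0,1.60,83.8,8.60,3.07,0
9,5.17,53.9,28.5,52.9,0,0
10,20.7,17.7,17.2,56.5,0,0
11,83.9,0.267,25.1,45.9,1.47,0
12,26.6,23.5,35.1,48.4,0,0
13,85.1,0.167,72.6,13.1,0.0333,0
14,63.0,0.600,32.5,43.0,0,0
15,2.73,69.4,6.87,78.3,0,0
16,51.7,7.90,10.5,77.5,24.8,0
17,0.0667,83.5,30.2,37.7,0,0
18,67.8,1.77,76.1,10.1,0,0
19,0,100,1.77,91.5,0,61.8
20,7.20,55.6,51.8,27.6,0,0
21,41.6,7.53,58.1,16.0,0,0
22,0,99.5,2.20,94.2,0,4.17
23,0.400,88.7,60.3,21.5,0,22.9
24,47.7,1.70,34.7,23.1,0,0
25,3.13,73.0,4.43,86.4,0,0
26,1.33,70.7,19.6,64.3,0,0
27,0.433,86.3,3.03,91.7,0,0
28,77.5,0.800,86.8,2.67,2.87,0
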