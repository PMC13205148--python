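line_id,D,MNND,rank,KL,KW,LWR,PH,EH,EPR,TPN,TBL,LUL,LUT,clade,ancestry
SHT18,0.8664,50.84,1,7.67,6.30,1.22,58.00,9.17,0.16,5.33,7.67,10.00,7.00,Clade II,Ancestry 2
SHT27,0.8517,49.14,2,6.86,6.24,1.10,66.13,8.17,0.12,5.67,7.53,9.77,7.34,Clade II,Ancestry 7
SHT19,0.8420,53.80,3,7.53,6.08,1.24,63.00,10.67,0.17,5.00,8.67,11.33,8.63,Clade II,Ancestry 2
SHT45,0.8217,52.67,4,8.28,6.42,1.29,61.67,11.67,0.19,6.00,9.00,14.67,10.67,Clade I,Ancestry 5
SHT26,0.8126,53.39,5,6.84,6.03,1.13,58.00,10.00,0.17,5.00,12.17,12.17,8.97,Clade II,Ancestry 7
SHN38,0.8077,61.46,6,7.33,6.13,1.19,92.00,14.00,0.16,3.67,7.17,13.50,11.67,Clade XI,Ancestry 2
SHN39,0.8030,56.17,7,7.49,6.22,1.20,73.00,15.00,0.20,5.67,7.67,13.17,10.50,Clade XII,Ancestry 4
SHT34,0.7972,48.54,8,7.67,6.52,1.18,71.67,15.00,0.21,3.00,9.67,15.00,13.33,Clade I,Ancestry 5
SHT24,0.7906,48.33,9,6.88,6.23,1.10,79.67,15.33,0.19,3.33,7.40,15.50,12.50,Clade II,Ancestry 7
SHN69,0.7726,67.69,10,7.26,6.69,1.09,70.17,13.00,0.18,4.67,11.83,16.33,13.33,Clade VIII,Ancestry 4
SHT28,0.7702,47.45,11,6.94,6.21,1.12,76.00,13.33,0.18,11.00,7.57,12.67,8.83,Clade I,Ancestry 7
SHT6,0.7691,53.88,12,8.10,7.30,1.11,87.27,6.67,0.08,8.33,11.17,20.27,13.87,Clade I,Ancestry 9
SHTN6,0.7655,57.38,13,8.91,7.46,1.20,76.67,10.67,0.14,4.33,11.97,22.80,18.83,Clade I,Ancestry 9
SHT44,0.7651,52.32,14,8.39,6.57,1.28,74.33,9.00,0.12,7.67,11.67,21.00,15.50,Clade I,Ancestry 5
SHT38,0.7644,43.87,15,7.63,6.34,1.21,86.67,17.00,0.20,2.00,11.27,17.93,15.40,Clade I,Ancestry 5
SHT17,0.7601,52.30,16,6.77,5.78,1.18,77.33,12.33,0.16,6.33,10.67,17.00,13.17,Clade II,Ancestry 5
SHN59,0.7472,64.12,17,8.05,7.10,1.13,100.00,23.00,0.23,5.67,8.00,16.33,12.33,Clade II,Ancestry 3
SHT20,0.7428,54.38,18,7.50,6.10,1.23,103.00,15.67,0.15,3.67,12.50,18.50,15.17,Clade I,Ancestry 5
SHT46,0.7418,54.23,19,8.77,6.62,1.33,101.67,13.67,0.13,3.33,13.00,22.23,19.33,Clade I,Ancestry 5
SHT37,0.7390,52.85,20,7.73,6.19,1.25,94.33,19.33,0.21,11.00,8.97,15.37,8.27,Clade V,Ancestry 5
SHN16,0.7385,57.25,21,7.70,7.28,1.06,79.33,19.00,0.24,1.67,12.50,19.67,17.33,Clade I,Ancestry 4
SHT58,0.7370,54.32,22,9.43,7.94,1.18,78.90,12.33,0.15,6.67,15.20,22.03,18.00,Clade I,Ancestry 2
SHN17,0.7365,59.19,23,7.97,7.43,1.07,85.67,11.93,0.14,2.00,14.50,22.17,20.97,Clade I,Ancestry 4
SHT5,0.7355,56.34,24,7.54,6.30,1.19,117.33,6.17,0.05,3.00,14.83,22.37,19.07,Clade II,Ancestry 5
SHT108,0.7351,66.43,25,8.69,7.19,1.21,111.00,16.67,0.15,3.00,12.00,22.33,18.00,Clade III,Ancestry 3
SHT47,0.7349,54.72,26,8.28,6.44,1.28,100.67,16.00,0.16,3.33,11.00,22.47,19.17,Clade VI,Ancestry 8
SHT88,0.7314,60.09,27,10.76,8.31,1.30,107.67,21.33,0.20,4.33,14.00,22.67,17.33,Clade II,Ancestry 5
SHT60,0.7304,60.30,28,7.05,6.14,1.15,94.67,11.67,0.12,3.33,19.10,16.17,15.33,Clade X,Ancestry 5
SHN60,0.7272,61.97,29,7.55,6.62,1.14,90.33,33.67,0.37,3.33,7.83,14.87,10.67,Clade X,Ancestry 3
SHN79,0.7189,65.04,30,8.57,8.10,1.06,131.67,20.00,0.15,3.33,11.67,20.33,16.83,Clade I,Ancestry 5
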