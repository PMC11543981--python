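patient_id,age,psa_ng_ml,gleason_score,mitnm,visual_pirads,prediction,dl_pirads,dice,activity_mbq
1,77,18.9,9,"T4, N1b, M1b",5,0.993,5,0.441,166
2,55,63.8,7b,"T3b, N1b, M0",5,0.988,5,0.433,239
3,64,5.2,9,"T2u, N0, M0",5,0.999,5,0.696,194
4,72,5.4,9,"T2u, N0, M0",5,0.949,5,0.561,176
5,48,4.0,6,"T0, N0, M0",2,0.05,2,,241
6,69,33.2,9,"T3b, N1a, M0",5,0.42,4,0.139,229
7,70,63.0,9,"T3b, N1b, M1b",5,0.45,4,0.382,242
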