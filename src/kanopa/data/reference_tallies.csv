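stratum,n,feature_code,A,M,O,I,R,Q,category_strength,total_strength,classification
total,103,A30,28,15,23,33,1,3,5,64,"X(I, A)"
pa_medium,18,A5,4,3,5,6,0,0,6,67,"X(I, O)"
pa_medium,18,A10,4,7,2,5,0,0,11,72,M
pa_medium,18,A11,6,5,1,6,0,0,0,67,"X(A, I)"
pa_medium,18,A20,4,5,3,6,0,0,6,67,"X(I, M)"
pa_medium,18,A23,2,3,6,7,0,0,6,61,"X(I, O)"
pa_medium,18,A29,4,1,6,7,0,0,6,61,"X(I, O)"
pa_low,22,A1,1,11,2,8,0,0,14,64,M
pa_low,22,A2,1,8,4,8,0,1,0,59,M
pa_low,22,A6,2,7,5,8,0,0,5,64,"X(I, M)"
pa_low,22,A7,3,6,7,5,1,0,5,73,"X(O, M)"
pa_low,22,A8,4,7,4,7,0,0,0,68,"X(M, I)"
pa_low,22,A9,3,7,4,8,0,0,5,64,"X(I, M)"
pa_low,22,A10,3,6,7,5,0,1,5,73,"X(O, M)"
pa_low,22,A12,5,6,5,5,1,0,5,73,"X(M, A, O, I)"
pa_low,22,A13,3,8,5,6,0,0,9,73,M
pa_low,22,A14,3,6,8,3,1,1,9,77,O
pa_low,22,A15,4,7,7,3,0,1,0,82,"X(M, O)"
pa_low,22,A20,4,5,6,7,0,0,5,68,"X(I, O)"
pa_low,22,A21,4,7,7,3,0,1,0,82,"X(M, O)"
pa_low,22,A22,5,8,6,3,0,0,9,86,M
pa_low,22,A23,4,6,7,4,1,0,5,77,"X(O, M)"
pa_low,22,A24,6,6,4,6,0,0,0,73,"X(A, M, I)"
pa_low,22,A25,4,8,5,5,0,0,14,77,M
pa_low,22,A26,4,9,5,4,0,0,18,82,M
pa_low,22,A29,7,7,5,3,0,0,0,86,"X(A, M)"
pa_low,22,A30,7,7,5,3,0,0,0,86,"X(A, M)"
pa_low,22,A52,6,7,3,6,0,0,5,73,"X(M, A, I)"
mpse_high,35,A2,6,10,7,11,0,1,3,66,"X(I, M)"
mpse_high,35,A10,6,10,8,10,0,1,0,69,"X(M, I)"
mpse_high,35,A12,6,5,11,12,0,1,3,63,"X(I, O)"
mpse_high,35,A13,7,7,10,9,0,2,3,69,"X(O, I)"
mpse_high,35,A14,6,6,11,10,0,2,3,66,"X(O, I)"
mpse_high,35,A15,5,8,10,10,0,2,0,66,"X(O, I)"
mpse_high,35,A21,7,5,10,11,0,2,3,63,"X(I, O)"
mpse_high,35,A22,4,3,14,12,1,1,6,60,"X(O, I)"
mpse_high,35,A23,6,3,14,10,0,2,11,66,O
mpse_high,35,A25,6,4,12,11,0,2,3,63,"X(O, I)"
mpse_high,35,A26,5,6,13,9,0,2,11,69,O
mpse_high,35,A29,7,3,15,8,0,2,20,71,O
mpse_high,35,A30,9,3,13,7,1,2,11,71,O
mpse_high,35,A52,6,6,10,12,0,1,6,63,"X(I, O)"
mpse_medium,32,A15,3,12,4,12,0,1,0,59,M
mpse_medium,32,A22,7,12,5,8,0,0,13,75,M
mpse_medium,32,A23,6,10,4,10,2,0,0,63,"X(M, I)"
mpse_medium,32,A25,6,13,3,10,0,0,9,69,M
mpse_medium,32,A26,4,13,3,12,0,0,3,63,"X(M, I)"
mpse_medium,32,A52,7,12,3,10,0,0,6,69,M
mpse_low,35,A30,12,4,7,12,0,0,0,66,"X(A, I)"
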