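module,age_min,age_max,raw_min,raw_max,css
1,2,5,0,2,1
1,2,5,3,4,2
1,2,5,5,6,3
1,2,5,7,8,4
1,2,5,9,10,5
1,2,5,11,13,6
1,2,5,14,16,7
1,2,5,17,19,8
1,2,5,20,23,9
1,2,5,24,28,10
1,6,8,0,3,1
1,6,8,4,5,2
1,6,8,6,7,3
1,6,8,8,9,4
1,6,8,10,11,5
1,6,8,12,14,6
1,6,8,15,17,7
1,6,8,18,20,8
1,6,8,21,24,9
1,6,8,25,28,10
2,3,6,0,2,1
2,3,6,3,4,2
2,3,6,5,6,3
2,3,6,7,8,4
2,3,6,9,10,5
2,3,6,11,13,6
2,3,6,14,16,7
2,3,6,17,19,8
2,3,6,20,23,9
2,3,6,24,28,10
2,7,10,0,3,1
2,7,10,4,5,2
2,7,10,6,7,3
2,7,10,8,9,4
2,7,10,10,11,5
2,7,10,12,14,6
2,7,10,15,17,7
2,7,10,18,20,8
2,7,10,21,24,9
2,7,10,25,28,10
3,5,10,0,2,1
3,5,10,3,4,2
3,5,10,5,6,3
3,5,10,7,8,4
3,5,10,9,10,5
3,5,10,11,13,6
3,5,10,14,16,7
3,5,10,17,19,8
3,5,10,20,23,9
3,5,10,24,28,10
3,11,16,0,3,1
3,11,16,4,5,2
3,11,16,6,7,3
3,11,16,8,9,4
3,11,16,10,11,5
3,11,16,12,14,6
3,11,16,15,17,7
3,11,16,18,20,8
3,11,16,21,24,9
3,11,16,25,28,10
4,16,25,0,2,1
4,16,25,3,4,2
4,16,25,5,6,3
4,16,25,7,8,4
4,16,25,9,10,5
4,16,25,11,13,6
4,16,25,14,16,7
4,16,25,17,19,8
4,16,25,20,23,9
4,16,25,24,28,10
4,26,40,0,3,1
4,26,40,4,5,2
4,26,40,6,7,3
4,26,40,8,9,4
4,26,40,10,11,5
4,26,40,12,14,6
4,26,40,15,17,7
4,26,40,18,20,8
4,26,40,21,24,9
4,26,40,25,28,10
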