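patient_id,reader_id,occasion,score
1,R1,1,11
1,R1,2,13
1,R2,1,14
1,R2,2,13
2,R1,1,16
2,R1,2,17
2,R2,1,17
2,R2,2,18
3,R1,1,2
3,R1,2,2
3,R2,1,2
3,R2,2,2
4,R1,1,7
4,R1,2,5
4,R2,1,7
4,R2,2,7
5,R1,1,26
5,R1,2,27
5,R2,1,25
5,R2,2,25
6,R1,1,16
6,R1,2,12
6,R2,1,11
6,R2,2,14
7,R1,1,6
7,R1,2,6
7,R2,1,9
7,R2,2,10
8,R1,1,6
8,R1,2,6
8,R2,1,6
8,R2,2,6
9,R1,1,7
9,R1,2,6
9,R2,1,7
9,R2,2,7
10,R1,1,2
10,R1,2,2
10,R2,1,5
10,R2,2,4
11,R1,1,12
11,R1,2,14
11,R2,1,13
11,R2,2,12
12,R1,1,9
12,R1,2,10
12,R2,1,8
12,R2,2,6
13,R1,1,14
13,R1,2,14
13,R2,1,13
13,R2,2,13
14,R1,1,7
14,R1,2,7
14,R2,1,7
14,R2,2,9
15,R1,1,3
15,R1,2,5
15,R2,1,11
15,R2,2,11
16,R1,1,8
16,R1,2,8
16,R2,1,6
16,R2,2,6
17,R1,1,13
17,R1,2,12
17,R2,1,9
17,R2,2,10
18,R1,1,5
18,R1,2,4
18,R2,1,5
18,R2,2,5
19,R1,1,4
19,R1,2,4
19,R2,1,4
19,R2,2,5
20,R1,1,14
20,R1,2,13
20,R2,1,11
20,R2,2,11
21,R1,1,6
21,R1,2,6
21,R2,1,6
21,R2,2,8
22,R1,1,6
22,R1,2,5
22,R2,1,6
22,R2,2,6
23,R1,1,14
23,R1,2,10
23,R2,1,10
23,R2,2,12
24,R1,1,9
24,R1,2,11
24,R2,1,10
24,R2,2,8
25,R1,1,11
25,R1,2,11
25,R2,1,10
25,R2,2,10
26,R1,1,4
26,R1,2,4
26,R2,1,4
26,R2,2,6
27,R1,1,10
27,R1,2,12
27,R2,1,13
27,R2,2,12
28,R1,1,13
28,R1,2,14
28,R2,1,14
28,R2,2,15
29,R1,1,3
29,R1,2,2
29,R2,1,3
29,R2,2,3
30,R1,1,11
30,R1,2,10
30,R2,1,11
30,R2,2,11
31,R1,1,7
31,R1,2,7
31,R2,1,6
31,R2,2,7
32,R1,1,8
32,R1,2,9
32,R2,1,8
32,R2,2,7
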