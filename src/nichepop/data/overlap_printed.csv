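i,j,overlap
2,1,0.71
3,1,0.60
3,2,0.92
4,1,0.44
4,2,0.74
4,3,0.91
5,1,0.88
5,2,0.41
5,3,0.25
5,4,0.00
6,1,0.89
6,2,0.40
6,3,0.25
6,4,0.00
6,5,1.00
7,1,0.86
7,2,0.27
7,3,0.17
7,4,0.00
7,5,0.97
7,6,0.97
8,1,0.94
8,2,0.62
8,3,0.48
8,4,0.21
8,5,0.97
8,6,0.96
8,7,0.90
9,1,0.86
9,2,0.28
9,3,0.17
9,4,0.00
9,5,0.97
9,6,0.98
9,7,1.00
9,8,0.91
10,1,0.46
10,2,0.74
10,3,0.84
10,4,0.97
10,5,0.00
10,6,0.00
10,7,0.00
10,8,0.19
10,9,0.00
11,1,0.67
11,2,0.72
11,3,0.50
11,4,0.00
11,5,0.73
11,6,0.71
11,7,0.53
11,8,0.82
11,9,0.54
11,10,0.07
12,1,0.44
12,2,0.74
12,3,0.90
12,4,1.00
12,5,0.00
12,6,0.00
12,7,0.00
12,8,0.21
12,9,0.00
12,10,0.98
12,11,0.10
13,1,0.85
13,2,0.45
13,3,0.49
13,4,0.30
13,5,0.89
13,6,0.87
13,7,0.89
13,8,0.90
13,9,0.89
13,10,0.21
13,11,0.58
13,12,0.29
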