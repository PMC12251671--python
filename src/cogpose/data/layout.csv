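index,name,parent,side,swap,group
0,nose,5,C,0,body
1,left_eye,0,L,2,body
2,right_eye,0,R,1,body
3,left_ear,1,L,4,body
4,right_ear,2,R,3,body
5,left_shoulder,11,L,6,body
6,right_shoulder,12,R,5,body
7,left_elbow,5,L,8,body
8,right_elbow,6,R,7,body
9,left_wrist,7,L,10,body
10,right_wrist,8,R,9,body
11,left_hip,-1,L,12,body
12,right_hip,11,R,11,body
13,left_knee,11,L,14,body
14,right_knee,12,R,13,body
15,left_ankle,13,L,16,body
16,right_ankle,14,R,15,body
17,left_big_toe,15,L,20,foot
18,left_small_toe,15,L,21,foot
19,left_heel,15,L,22,foot
20,right_big_toe,16,R,17,foot
21,right_small_toe,16,R,18,foot
22,right_heel,16,R,19,foot
23,face_0,0,R,39,face
24,face_1,0,R,38,face
25,face_2,0,R,37,face
26,face_3,0,R,36,face
27,face_4,0,R,35,face
28,face_5,0,R,34,face
29,face_6,0,R,33,face
30,face_7,0,R,32,face
31,face_8,0,C,31,face
32,face_9,0,L,30,face
33,face_10,0,L,29,face
34,face_11,0,L,28,face
35,face_12,0,L,27,face
36,face_13,0,L,26,face
37,face_14,0,L,25,face
38,face_15,0,L,24,face
39,face_16,0,L,23,face
40,face_17,0,R,49,face
41,face_18,0,R,48,face
42,face_19,0,R,47,face
43,face_20,0,R,46,face
44,face_21,0,R,45,face
45,face_22,0,L,44,face
46,face_23,0,L,43,face
47,face_24,0,L,42,face
48,face_25,0,L,41,face
49,face_26,0,L,40,face
50,face_27,0,C,50,face
51,face_28,0,C,51,face
52,face_29,0,C,52,face
53,face_30,0,C,53,face
54,face_31,0,R,58,face
55,face_32,0,R,57,face
56,face_33,0,C,56,face
57,face_34,0,L,55,face
58,face_35,0,L,54,face
59,face_36,0,R,68,face
60,face_37,0,R,67,face
61,face_38,0,R,66,face
62,face_39,0,R,65,face
63,face_40,0,R,70,face
64,face_41,0,R,69,face
65,face_42,0,L,62,face
66,face_43,0,L,61,face
67,face_44,0,L,60,face
68,face_45,0,L,59,face
69,face_46,0,L,64,face
70,face_47,0,L,63,face
71,face_48,0,R,77,face
72,face_49,0,R,76,face
73,face_50,0,R,75,face
74,face_51,0,C,74,face
75,face_52,0,L,73,face
76,face_53,0,L,72,face
77,face_54,0,L,71,face
78,face_55,0,R,82,face
79,face_56,0,R,81,face
80,face_57,0,C,80,face
81,face_58,0,L,79,face
82,face_59,0,L,78,face
83,face_60,0,R,87,face
84,face_61,0,R,86,face
85,face_62,0,C,85,face
86,face_63,0,L,84,face
87,face_64,0,L,83,face
88,face_65,0,R,90,face
89,face_66,0,C,89,face
90,face_67,0,L,88,face
91,left_hand_0,9,L,112,left_hand
92,left_hand_1,91,L,113,left_hand
93,left_hand_2,92,L,114,left_hand
94,left_hand_3,93,L,115,left_hand
95,left_hand_4,94,L,116,left_hand
96,left_hand_5,91,L,117,left_hand
97,left_hand_6,96,L,118,left_hand
98,left_hand_7,97,L,119,left_hand
99,left_hand_8,98,L,120,left_hand
100,left_hand_9,91,L,121,left_hand
101,left_hand_10,100,L,122,left_hand
102,left_hand_11,101,L,123,left_hand
103,left_hand_12,102,L,124,left_hand
104,left_hand_13,91,L,125,left_hand
105,left_hand_14,104,L,126,left_hand
106,left_hand_15,105,L,127,left_hand
107,left_hand_16,106,L,128,left_hand
108,left_hand_17,91,L,129,left_hand
109,left_hand_18,108,L,130,left_hand
110,left_hand_19,109,L,131,left_hand
111,left_hand_20,110,L,132,left_hand
112,right_hand_0,10,R,91,right_hand
113,right_hand_1,112,R,92,right_hand
114,right_hand_2,113,R,93,right_hand
115,right_hand_3,114,R,94,right_hand
116,right_hand_4,115,R,95,right_hand
117,right_hand_5,112,R,96,right_hand
118,right_hand_6,117,R,97,right_hand
119,right_hand_7,118,R,98,right_hand
120,right_hand_8,119,R,99,right_hand
121,right_hand_9,112,R,100,right_hand
122,right_hand_10,121,R,101,right_hand
123,right_hand_11,122,R,102,right_hand
124,right_hand_12,123,R,103,right_hand
125,right_hand_13,112,R,104,right_hand
126,right_hand_14,125,R,105,right_hand
127,right_hand_15,126,R,106,right_hand
128,right_hand_16,127,R,107,right_hand
129,right_hand_17,112,R,108,right_hand
130,right_hand_18,129,R,109,right_hand
131,right_hand_19,130,R,110,right_hand
132,right_hand_20,131,R,111,right_hand
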