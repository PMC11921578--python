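item,subscale,reverse_keyed
1,social_skills,True
2,attention_switching,False
3,imagination,True
4,attention_switching,False
5,attention_to_detail,False
6,attention_to_detail,False
7,communication,False
8,imagination,True
9,attention_to_detail,False
10,attention_switching,True
11,social_skills,True
12,attention_to_detail,False
13,social_skills,False
14,imagination,True
15,social_skills,True
16,attention_switching,False
17,communication,True
18,communication,False
19,attention_to_detail,False
20,imagination,False
21,imagination,False
22,social_skills,False
23,attention_to_detail,False
24,imagination,True
25,attention_switching,True
26,communication,False
27,communication,True
28,attention_to_detail,True
29,attention_to_detail,True
30,attention_to_detail,True
31,communication,True
32,attention_switching,True
33,communication,False
34,attention_switching,True
35,communication,False
36,social_skills,True
37,attention_switching,True
38,communication,True
39,communication,False
40,imagination,True
41,imagination,False
42,imagination,False
43,attention_switching,False
44,social_skills,True
45,social_skills,False
46,attention_switching,False
47,social_skills,True
48,social_skills,True
49,attention_to_detail,True
50,imagination,True
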