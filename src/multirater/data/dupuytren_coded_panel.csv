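case,chatgpt,gemini,perplexity,deepseek,copilot,surgeon1,surgeon2,surgeon3
1,1/2,1/3,1/2,1/2,2,1,7,1
2,1/2/4,1/2/4,1/2/4,1/2,4,1,7,7
3,4/5,4/5,4/5,7/2,4,4,1,7
4,8,8,8,8,8,8,2/6/8,8
5,8,8,8,1/2,2,1,1,1
6,8,8,8,8,8,8,8/1,8
7,1/2/4,1/2/4,1/2/4,7,2,4,5/7,7
8,2/1/4,2/1/4,2/1,4,4,1,7,7
9,6,6,5/6,4,4,4,10/5,10
10,9/10,9/10,1/2,4,4,1,1,10/5
11,5/11,5/11,5,4,4,1,5,7
12,1/2/4,1/2/4,2/7,4,4,1,4/1,7
13,6,6,5,8,8,4,5/10,10
14,8,8,8,4,4,8,6,4
15,1/2/4,1/2/4,4/5,2,2,1,1,7
16,8,8,8,1/2,8,8,8,1
17,8,8,8,2,2,8,8,1
18,8,1/2,8,1/2,8,1,1,1
19,1/2/4,1/2/4,2/7,4,4,1,1,7
20,1/2/4,1/2/4,7/2,4,4,4,6,10
21,4/5,4/5,5,4,4,4,7,7
22,1/2,1/2,1/2,2,2,1,7/1,4
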