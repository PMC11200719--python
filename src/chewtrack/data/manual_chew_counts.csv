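video_id,duration_s,assessed,measured
1,74,83,79
2,108,122,119
3,164,130,120
4,231,267,277
5,248,291,283
6,300,393,376
7,259,340,321
8,348,379,345
9,256,214,198
10,242,280,257
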