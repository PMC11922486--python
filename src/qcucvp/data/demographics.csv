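#,Age (years),Height (cm),Weight (kg),Sex
1,43,165,63.9,Male
2,48,191,118.7,Male
3,55,178,84.5,Male
4,53,173,98.1,Male
5,78,175,77.7,Male
6,81,166,86.3,Male
7,63,163,89.6,Female
8,78,180,78.2,Male
9,78,170,75.9,Male
10,53,170,93.1,Female
11,70,168,80.1,Male
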