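item,category,text
1,gastrointestinal,I felt sick to my stomach
2,gastrointestinal,I felt queasy
3,gastrointestinal,I felt nauseated
4,gastrointestinal,I felt as if I may vomit
5,central,I felt faint-like
6,central,I felt lightheaded
7,central,I felt dizzy
8,central,I felt like I was spinning
9,central,I felt disoriented
10,peripheral,I felt sweaty
11,peripheral,I felt clammy/cold sweat
12,peripheral,I felt hot/warm
13,sopite,I felt annoyed/irritated
14,sopite,I felt drowsy
15,sopite,I felt tired/fatigued
16,sopite,I felt uneasy
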