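subject,timepoint,consensus,rater1,rater2
S1,1h,S,S,S
S2,1h,I,I,I
S3,1h,S,S,S
S4,1h,S,S,S
S5,1h,S,S,S
S6,1h,I,I,I
S1,2h,I,I,I
S2,2h,I,I,I
S3,2h,S,S,S
S4,2h,I,I,I
S5,2h,S,S,S
S6,2h,W,W,W
S1,3h,S,I,S
S2,3h,S,S,I
S3,3h,S,I,S
S4,3h,I,I,I
S5,3h,S,S,S
S6,3h,I,I,I
S1,4h,I,I,S
S2,4h,S,S,S
S3,4h,I,I,S
S4,4h,S,S,W
S5,4h,S,S,S
S6,4h,S,S,W
S1,12h,I,I,S
S2,12h,I,I,I
S3,12h,I,I,I
S4,12h,I,I,I
S5,12h,S,S,S
S6,12h,S,S,S
S1,1d,I,I,I
S2,1d,S,S,S
S3,1d,W,W,W
S4,1d,W,W,W
S5,1d,S,S,S
S6,1d,I,I,I
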