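sample_id,gene,replicate,plate_id,ct
S1,ACTB,1,plate1,20.0
S1,ACTB,2,plate1,20.2
S2,ACTB,1,plate1,20.1
S2,ACTB,2,plate1,19.9
S3,ACTB,1,plate2,20.0
S3,ACTB,2,plate2,20.0
S4,ACTB,1,plate2,19.8
S4,ACTB,2,plate2,20.2
S5,ACTB,1,plate3,20.1
S5,ACTB,2,plate3,26.1
S6,ACTB,1,plate3,Undetermined
S6,ACTB,2,plate3,Undetermined
S1,HPRT,1,plate1,24.0
S1,HPRT,2,plate1,24.2
S2,HPRT,1,plate1,24.1
S2,HPRT,2,plate1,23.9
S3,HPRT,1,plate2,Undetermined
S3,HPRT,2,plate2,24.3
S4,HPRT,1,plate2,24.0
S4,HPRT,2,plate2,24.0
S5,HPRT,1,plate3,24.2
S5,HPRT,2,plate3,24.0
S6,HPRT,1,plate3,24.1
S6,HPRT,2,plate3,24.1
S1,AVL9,1,plate1,26.0
S1,AVL9,2,plate1,26.2
S2,AVL9,1,plate1,25.9
S2,AVL9,2,plate1,26.1
S3,AVL9,1,plate2,26.1
S3,AVL9,2,plate2,26.1
S4,AVL9,1,plate2,Undetermined
S4,AVL9,2,plate2,26.3
S5,AVL9,1,plate3,26.0
S5,AVL9,2,plate3,26.0
S6,AVL9,1,plate3,26.2
S6,AVL9,2,plate3,26.0
S1,PCMTD2,1,plate1,27.0
S1,PCMTD2,2,plate1,27.2
S2,PCMTD2,1,plate1,27.1
S2,PCMTD2,2,plate1,33.0
S3,PCMTD2,1,plate2,27.0
S3,PCMTD2,2,plate2,26.8
S4,PCMTD2,1,plate2,27.1
S4,PCMTD2,2,plate2,27.1
S5,PCMTD2,1,plate3,26.9
S5,PCMTD2,2,plate3,27.1
S6,PCMTD2,1,plate3,27.0
S6,PCMTD2,2,plate3,27.0
S1,NCLN,1,plate1,29.0
S1,NCLN,2,plate1,29.2
S2,NCLN,1,plate1,29.1
S2,NCLN,2,plate1,28.9
S3,NCLN,1,plate2,Undetermined
S3,NCLN,2,plate2,Undetermined
S4,NCLN,1,plate2,29.0
S4,NCLN,2,plate2,29.0
S5,NCLN,1,plate3,28.8
S5,NCLN,2,plate3,29.2
S6,NCLN,1,plate3,29.1
S6,NCLN,2,plate3,28.9
S1,MAP4K4,1,plate1,28.0
S1,MAP4K4,2,plate1,28.1
S2,MAP4K4,1,plate1,28.1
S2,MAP4K4,2,plate1,28.0
S3,MAP4K4,1,plate2,28.0
S3,MAP4K4,2,plate2,28.0
S4,MAP4K4,1,plate2,28.0
S4,MAP4K4,2,plate2,28.1
S5,MAP4K4,1,plate3,28.1
S5,MAP4K4,2,plate3,28.0
S6,MAP4K4,1,plate3,28.0
S6,MAP4K4,2,plate3,28.1
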