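vendor,hla_class,allele
LC,I,A*02:02
LC,I,A*02:05
LC,I,B*07:03
LC,I,B*15:18
LC,I,B*27:03
LC,I,B*35:08
LC,I,B*82:01
LC,I,Cw*04:03
LC,I,Cw*07:01
LC,I,Cw*08:02
LC,I,Cw*12:02
LC,I,Cw*18:01
LS,I,A*02:06
LS,I,A*30:02
LS,I,A*34:01
LS,I,B*13:01
LS,I,B*15:10
LS,I,B*40:06
LS,I,B*51:02
LS,I,B*57:03
LS,I,B*82:02
LS,I,Cw*03:02
LS,I,Cw*12:03
LS,I,Cw*18:02
LC,II,DRB1*03:03
LC,II,DRB1*08:02
LC,II,DRB1*11:03
LC,II,DRB1*13:05
LC,II,DRB1*14:03
LC,II,DRB1*14:04
LC,II,DQB1*02:02\DQA1*03:02
LC,II,DQB1*02:02\DQA1*05:01
LC,II,DQB1*03:01\DQA1*03:02
LC,II,DQB1*03:01\DQA1*05:01
LC,II,DQB1*03:03\DQA1*04:01
LC,II,DQB1*03:03\DQA1*06:01
LC,II,DQB1*04:01\DQA1*04:01
LC,II,DQB1*04:01\DQA1*05:01
LC,II,DQB1*04:02\DQA1*03:01
LC,II,DQB1*04:02\DQA1*06:01
LC,II,DQB1*05:01\DQA1*01:02
LC,II,DQB1*05:03\DQA1*01:04
LC,II,DQB1*06:01\DQA1*01:04
LC,II,DQB1*06:01\DQA1*02:01
LC,II,DPB1*01:01\DPA1*02:02
LC,II,DPB1*01:01\DPA1*03:01
LC,II,DPB1*04:01\DPA1*01:03
LC,II,DPB1*04:01\DPA1*02:01
LC,II,DPB1*04:01\DPA1*02:02
LC,II,DPB1*04:01\DPA1*03:01
LC,II,DPB1*04:01\DPA1*04:01
LC,II,DPB1*04:02\DPA1*03:01
LC,II,DPB1*05:01\DPA1*03:01
LC,II,DPB1*11:01\DPA1*02:01
LC,II,DPB1*13:01\DPA1*04:01
LC,II,DPB1*18:01\DPA1*01:03
LC,II,DPB1*19:01\DPA1*02:01
LC,II,DPB1*28:01\DPA1*02:02
LS,II,DRB1*09:02
LS,II,DRB1*14:02
LS,II,DRB1*14:54
LS,II,DRB4*01:03
LS,II,DQB1*02:01\DQA1*03:01
LS,II,DQB1*02:01\DQA1*04:01
LS,II,DQB1*03:01\DQA1*02:01
LS,II,DQB1*03:03\DQA1*03:01
LS,II,DQB1*03:01\DQA1*05:03
LS,II,DQB1*03:01\DQA1*05:05
LS,II,DQB1*03:03\DQA1*02:01
LS,II,DQB1*04:01\DQA1*03:03
LS,II,DQB1*04:02\DQA1*02:01
LS,II,DQB1*06:02\DQA1*01:01
LS,II,DQB1*06:09\DQA1*01:02
LS,II,DPB1*03:01\DPA1*01:05
LS,II,DPB1*03:01\DPA1*02:01
LS,II,DPB1*04:01\DPA1*01:03
LS,II,DPB1*06:01\DPA1*02:01
LS,II,DPB1*10:01\DPA1*02:02
LS,II,DPB1*11:01\DPA1*01:03
LS,II,DPB1*11:01\DPA1*02:02
LS,II,DPB1*13:01\DPA1*02:02
LS,II,DPB1*13:01\DPA1*03:01
LS,II,DPB1*18:01\DPA1*01:04
LS,II,DPB1*18:01\DPA1*01:05
LS,II,DPB1*18:01\DPA1*02:01
LS,II,DPB1*19:01\DPA1*01:03
LS,II,DPB1*09:01\DPA1*02:01
LS,II,DPB1*20:01\DPA1*03:01
LS,II,DPB1*23:01\DPA1*02:01
LS,II,DPB1*28:01\DPA1*01:03
LS,II,DPB1*28:01\DPA1*01:05
LS,II,DPB1*28:01\DPA1*04:01
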