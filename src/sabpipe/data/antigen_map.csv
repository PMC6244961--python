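allele,base
A*01:01,A1
A*02:01,A2
A*02:02,A2
A*02:03,A2
A*02:05,A2
A*02:06,A2
A*03:01,A3
A*11:01,A11
A*11:02,A11
A*23:01,A23
A*24:02,A24
A*24:03,A24
A*25:01,A25
A*26:01,A26
A*29:01,A29
A*29:02,A29
A*30:01,A30
A*30:02,A30
A*31:01,A31
A*32:01,A32
A*33:01,A33
A*33:03,A33
A*34:01,A34
A*34:02,A34
A*36:01,A36
A*43:01,A43
A*66:01,A66
A*66:02,A66
A*68:01,A68
A*68:02,A68
A*69:01,A69
A*74:01,A74
A*80:01,A80
B*07:02,B7
B*07:03,B7
B*08:01,B8
B*13:01,B13
B*13:02,B13
B*14:01,B64
B*14:02,B65
B*15:01,B62
B*15:02,B75
B*15:03,B72
B*15:10,B71
B*15:11,B75
B*15:12,B76
B*15:13,B77
B*15:16,B63
B*15:18,B71
B*18:01,B18
B*27:03,B27
B*27:05,B27
B*27:08,B27
B*35:01,B35
B*35:08,B35
B*37:01,B37
B*38:01,B38
B*39:01,B39
B*40:01,B60
B*40:02,B61
B*40:06,B61
B*41:01,B41
B*42:01,B42
B*44:02,B44
B*44:03,B44
B*45:01,B45
B*46:01,B46
B*47:01,B47
B*48:01,B48
B*49:01,B49
B*50:01,B50
B*51:01,B51
B*51:02,B51
B*52:01,B52
B*53:01,B53
B*54:01,B54
B*55:01,B55
B*56:01,B56
B*57:01,B57
B*57:03,B57
B*58:01,B58
B*59:01,B59
B*67:01,B67
B*73:01,B73
B*78:01,B78
B*81:01,B81
B*82:01,B82
B*82:02,B82
Cw*01:02,Cw1
Cw*02:02,Cw2
Cw*03:02,Cw10
Cw*03:03,Cw9
Cw*03:04,Cw10
Cw*04:01,Cw4
Cw*04:03,Cw4
Cw*05:01,Cw5
Cw*06:02,Cw6
Cw*07:01,Cw7
Cw*07:02,Cw7
Cw*08:01,Cw8
Cw*08:02,Cw8
Cw*12:02,Cw12
Cw*12:03,Cw12
Cw*14:02,Cw14
Cw*15:02,Cw15
Cw*16:02,Cw16
Cw*17:01,Cw17
Cw*18:01,Cw18
Cw*18:02,Cw18
DRB1*01:01,DR1
DRB1*03:01,DR17
DRB1*03:02,DR18
DRB1*03:03,DR18
DRB1*04:01,DR4
DRB1*04:03,DR4
DRB1*07:01,DR7
DRB1*08:01,DR8
DRB1*08:02,DR8
DRB1*09:01,DR9
DRB1*09:02,DR9
DRB1*10:01,DR10
DRB1*11:01,DR11
DRB1*11:03,DR11
DRB1*12:01,DR12
DRB1*13:01,DR13
DRB1*13:05,DR13
DRB1*14:01,DR14
DRB1*14:02,DR14
DRB1*14:03,DR14
DRB1*14:04,DR14
DRB1*14:54,DR14
DRB1*15:01,DR15
DRB1*16:01,DR16
DQB1*02:01,DQ2
DQB1*02:02,DQ2
DQB1*03:01,DQ7
DQB1*03:02,DQ8
DQB1*03:03,DQ9
DQB1*04:01,DQ4
DQB1*04:02,DQ4
DQB1*05:01,DQ5
DQB1*05:02,DQ5
DQB1*05:03,DQ5
DQB1*06:01,DQ6
DQB1*06:02,DQ6
DQB1*06:03,DQ6
DQB1*06:04,DQ6
DQB1*06:09,DQ6
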