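allele,ls_mfi,lc_mfi
NC,0,0
PC,12,0
B*07:02,862,0
B*07:03,,0
B*08:01,1226,0
B*13:01,6915,
B*13:02,2514,12
B*14:01,7805,0
B*14:02,1831,3
B*15:01,335,0
B*15:02,1935,0
B*15:03,1822,0
B*15:10,1010,
B*15:11,5165,
B*15:12,770,0
B*15:13,3135,0
B*15:16,3076,0
B*15:18,,0
B*18:01,3096,0
B*27:03,,0
B*27:05,634,0
B*27:08,1659,0
B*35:01,6128,0
B*35:08,,0
B*37:01,2650,0
B*38:01,2521,0
B*39:01,704,0
B*40:01,3429,0
B*40:02,2697,0
B*40:06,10684,
B*41:01,3739,0
B*42:01,347,0
B*44:02,3650,0
B*44:03,1829,0
B*45:01,1736,0
B*46:01,3572,0
B*47:01,2152,0
B*48:01,3262,10
B*49:01,1554,0
B*50:01,1799,0
B*51:01,2461,8
B*51:02,2695,
B*52:01,2146,0
B*53:01,5442,2
B*54:01,1662,0
B*55:01,2519,0
B*56:01,3662,0
B*57:01,2089,0
B*57:03,2260,
B*58:01,5268,0
B*59:01,3553,1
B*67:01,406,0
B*73:01,1423,2
B*78:01,2996,0
B*81:01,1525,0
B*82:01,3442,
B*82:02,,0
Cw*01:02,4066,1
Cw*02:02,7446,20
Cw*03:02,2889,
Cw*03:03,2458,0
Cw*03:04,4504,0
Cw*04:01,3337,8
Cw*04:03,,0
Cw*05:01,9124,24
Cw*06:02,5644,4
Cw*07:01,,27
Cw*07:02,870,297
Cw*08:01,6090,1
Cw*08:02,,3
Cw*12:02,,10
Cw*12:03,3562,
Cw*14:02,3937,0
Cw*15:02,4465,4
Cw*16:02,4648,0
Cw*17:01,8296,10
Cw*18:01,,0
Cw*18:02,8015,
A*01:01,933,0
A*02:01,339,0
A*02:02,,0
A*02:03,1018,0
A*02:05,,0
A*02:06,1230,
A*03:01,193,0
A*11:01,4782,0
A*11:02,537,0
A*23:01,133,0
A*24:02,716,0
A*24:03,2516,0
A*25:01,194,0
A*26:01,2221,0
A*29:01,1017,0
A*29:02,778,0
A*30:01,1496,0
A*30:02,1135,
A*31:01,396,0
A*32:01,515,0
A*33:01,1038,0
A*33:03,554,0
A*34:01,2616,
A*34:02,1535,0
A*36:01,1353,0
A*43:01,2479,0
A*66:01,1886,0
A*66:02,1454,0
A*68:01,713,0
A*68:02,1185,0
A*69:01,3128,0
A*74:01,652,0
A*80:01,3132,0
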