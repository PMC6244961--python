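vendor,lot,bead_id,allele_1,allele_2,control_flag
LS,10,LS001,B*07:02,,none
LS,10,LS002,B*08:01,,none
LS,10,LS003,B*13:01,,none
LS,10,LS004,B*13:02,,none
LS,10,LS005,B*14:01,,none
LS,10,LS006,B*14:02,,none
LS,10,LS007,B*15:01,,none
LS,10,LS008,B*15:02,,none
LS,10,LS009,B*15:03,,none
LS,10,LS010,B*15:10,,none
LS,10,LS011,B*15:11,,none
LS,10,LS012,B*15:12,,none
LS,10,LS013,B*15:13,,none
LS,10,LS014,B*15:16,,none
LS,10,LS015,B*18:01,,none
LS,10,LS016,B*27:05,,none
LS,10,LS017,B*27:08,,none
LS,10,LS018,B*35:01,,none
LS,10,LS019,B*37:01,,none
LS,10,LS020,B*38:01,,none
LS,10,LS021,B*39:01,,none
LS,10,LS022,B*40:01,,none
LS,10,LS023,B*40:02,,none
LS,10,LS024,B*40:06,,none
LS,10,LS025,B*41:01,,none
LS,10,LS026,B*42:01,,none
LS,10,LS027,B*44:02,,none
LS,10,LS028,B*44:03,,none
LS,10,LS029,B*45:01,,none
LS,10,LS030,B*46:01,,none
LS,10,LS031,B*47:01,,none
LS,10,LS032,B*48:01,,none
LS,10,LS033,B*49:01,,none
LS,10,LS034,B*50:01,,none
LS,10,LS035,B*51:01,,none
LS,10,LS036,B*51:02,,none
LS,10,LS037,B*52:01,,none
LS,10,LS038,B*53:01,,none
LS,10,LS039,B*54:01,,none
LS,10,LS040,B*55:01,,none
LS,10,LS041,B*56:01,,none
LS,10,LS042,B*57:01,,none
LS,10,LS043,B*57:03,,none
LS,10,LS044,B*58:01,,none
LS,10,LS045,B*59:01,,none
LS,10,LS046,B*67:01,,none
LS,10,LS047,B*73:01,,none
LS,10,LS048,B*78:01,,none
LS,10,LS049,B*81:01,,none
LS,10,LS050,B*82:01,,none
LS,10,LS051,Cw*01:02,,none
LS,10,LS052,Cw*02:02,,none
LS,10,LS053,Cw*03:02,,none
LS,10,LS054,Cw*03:03,,none
LS,10,LS055,Cw*03:04,,none
LS,10,LS056,Cw*04:01,,none
LS,10,LS057,Cw*05:01,,none
LS,10,LS058,Cw*06:02,,none
LS,10,LS059,Cw*07:02,,none
LS,10,LS060,Cw*08:01,,none
LS,10,LS061,Cw*12:03,,none
LS,10,LS062,Cw*14:02,,none
LS,10,LS063,Cw*15:02,,none
LS,10,LS064,Cw*16:02,,none
LS,10,LS065,Cw*17:01,,none
LS,10,LS066,Cw*18:02,,none
LS,10,LS067,A*01:01,,none
LS,10,LS068,A*02:01,,none
LS,10,LS069,A*02:03,,none
LS,10,LS070,A*02:06,,none
LS,10,LS071,A*03:01,,none
LS,10,LS072,A*11:01,,none
LS,10,LS073,A*11:02,,none
LS,10,LS074,A*23:01,,none
LS,10,LS075,A*24:02,,none
LS,10,LS076,A*24:03,,none
LS,10,LS077,A*25:01,,none
LS,10,LS078,A*26:01,,none
LS,10,LS079,A*29:01,,none
LS,10,LS080,A*29:02,,none
LS,10,LS081,A*30:01,,none
LS,10,LS082,A*30:02,,none
LS,10,LS083,A*31:01,,none
LS,10,LS084,A*32:01,,none
LS,10,LS085,A*33:01,,none
LS,10,LS086,A*33:03,,none
LS,10,LS087,A*34:01,,none
LS,10,LS088,A*34:02,,none
LS,10,LS089,A*36:01,,none
LS,10,LS090,A*43:01,,none
LS,10,LS091,A*66:01,,none
LS,10,LS092,A*66:02,,none
LS,10,LS093,A*68:01,,none
LS,10,LS094,A*68:02,,none
LS,10,LS095,A*69:01,,none
LS,10,LS096,A*74:01,,none
LS,10,LS097,A*80:01,,none
LS,10,LS-NC,,,negative_control
LS,10,LS-PC,,,positive_control
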