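vendor,lot,bead_id,allele_1,allele_2,control_flag
LC,3005613,LC001,B*07:02,,none
LC,3005613,LC002,B*07:03,,none
LC,3005613,LC003,B*08:01,,none
LC,3005613,LC004,B*13:02,,none
LC,3005613,LC005,B*14:01,,none
LC,3005613,LC006,B*14:02,,none
LC,3005613,LC007,B*15:01,,none
LC,3005613,LC008,B*15:02,,none
LC,3005613,LC009,B*15:03,,none
LC,3005613,LC010,B*15:12,,none
LC,3005613,LC011,B*15:13,,none
LC,3005613,LC012,B*15:16,,none
LC,3005613,LC013,B*15:18,,none
LC,3005613,LC014,B*18:01,,none
LC,3005613,LC015,B*27:03,,none
LC,3005613,LC016,B*27:05,,none
LC,3005613,LC017,B*27:08,,none
LC,3005613,LC018,B*35:01,,none
LC,3005613,LC019,B*35:08,,none
LC,3005613,LC020,B*37:01,,none
LC,3005613,LC021,B*38:01,,none
LC,3005613,LC022,B*39:01,,none
LC,3005613,LC023,B*40:01,,none
LC,3005613,LC024,B*40:02,,none
LC,3005613,LC025,B*41:01,,none
LC,3005613,LC026,B*42:01,,none
LC,3005613,LC027,B*44:02,,none
LC,3005613,LC028,B*44:03,,none
LC,3005613,LC029,B*45:01,,none
LC,3005613,LC030,B*46:01,,none
LC,3005613,LC031,B*47:01,,none
LC,3005613,LC032,B*48:01,,none
LC,3005613,LC033,B*49:01,,none
LC,3005613,LC034,B*50:01,,none
LC,3005613,LC035,B*51:01,,none
LC,3005613,LC036,B*52:01,,none
LC,3005613,LC037,B*53:01,,none
LC,3005613,LC038,B*54:01,,none
LC,3005613,LC039,B*55:01,,none
LC,3005613,LC040,B*56:01,,none
LC,3005613,LC041,B*57:01,,none
LC,3005613,LC042,B*58:01,,none
LC,3005613,LC043,B*59:01,,none
LC,3005613,LC044,B*67:01,,none
LC,3005613,LC045,B*73:01,,none
LC,3005613,LC046,B*78:01,,none
LC,3005613,LC047,B*81:01,,none
LC,3005613,LC048,B*82:02,,none
LC,3005613,LC049,Cw*01:02,,none
LC,3005613,LC050,Cw*02:02,,none
LC,3005613,LC051,Cw*03:03,,none
LC,3005613,LC052,Cw*03:04,,none
LC,3005613,LC053,Cw*04:01,,none
LC,3005613,LC054,Cw*04:03,,none
LC,3005613,LC055,Cw*05:01,,none
LC,3005613,LC056,Cw*06:02,,none
LC,3005613,LC057,Cw*07:01,,none
LC,3005613,LC058,Cw*07:02,,none
LC,3005613,LC059,Cw*08:01,,none
LC,3005613,LC060,Cw*08:02,,none
LC,3005613,LC061,Cw*12:02,,none
LC,3005613,LC062,Cw*14:02,,none
LC,3005613,LC063,Cw*15:02,,none
LC,3005613,LC064,Cw*16:02,,none
LC,3005613,LC065,Cw*17:01,,none
LC,3005613,LC066,Cw*18:01,,none
LC,3005613,LC067,A*01:01,,none
LC,3005613,LC068,A*02:01,,none
LC,3005613,LC069,A*02:02,,none
LC,3005613,LC070,A*02:03,,none
LC,3005613,LC071,A*02:05,,none
LC,3005613,LC072,A*03:01,,none
LC,3005613,LC073,A*11:01,,none
LC,3005613,LC074,A*11:02,,none
LC,3005613,LC075,A*23:01,,none
LC,3005613,LC076,A*24:02,,none
LC,3005613,LC077,A*24:03,,none
LC,3005613,LC078,A*25:01,,none
LC,3005613,LC079,A*26:01,,none
LC,3005613,LC080,A*29:01,,none
LC,3005613,LC081,A*29:02,,none
LC,3005613,LC082,A*30:01,,none
LC,3005613,LC083,A*31:01,,none
LC,3005613,LC084,A*32:01,,none
LC,3005613,LC085,A*33:01,,none
LC,3005613,LC086,A*33:03,,none
LC,3005613,LC087,A*34:02,,none
LC,3005613,LC088,A*36:01,,none
LC,3005613,LC089,A*43:01,,none
LC,3005613,LC090,A*66:01,,none
LC,3005613,LC091,A*66:02,,none
LC,3005613,LC092,A*68:01,,none
LC,3005613,LC093,A*68:02,,none
LC,3005613,LC094,A*69:01,,none
LC,3005613,LC095,A*74:01,,none
LC,3005613,LC096,A*80:01,,none
LC,3005613,LC-NC,,,negative_control
LC,3005613,LC-PC,,,positive_control
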