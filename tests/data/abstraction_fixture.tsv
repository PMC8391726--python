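word	degree
侶嶹	2.0264
姰庂昹	1.3803
岤刋	2.9875
偹滽奰	2.4582
撁	2.3231
棃洹暤	2.5005
橶夘垲	1.3711
剪姀嚮	2.6971
國	2.0275
唖	2.7860
偶圞娻	2.1738
傖	3.7374
濔俛	3.9597
榱夻埰	3.5584
戚律咑	3.0936
崂宮	2.1068
岬	3.1740
嬙佷曛	1.3743
廫	2.0908
倡汭垃	2.6762
喪攨	0.3646
徥会	3.1478
澿	3.0053
冷	1.7979
區汪	3.5276
晗呾勮	2.1669
嶬廱澾	3.3347
撷佘寸	1.9460
戹嚵	2.4782
徜厯圌	2.0249
栟曗先	2.6019
掃	2.0626
涙喞污	2.6959
坏	1.0595
叐宒崋	2.8886
剾	1.8946
嗇欈	2.9770
偖旁	2.2431
奣扵僊	2.7527
塗傗	2.7219
偫潙滅	1.9358
櫉俑	3.1754
濋墁喾	3.1183
儜屬	2.4358
嶑涵潄	2.7935
楌密	4.1747
捐搒坓	1.3207
崒渴労	3.0810
后	1.6143
樰	2.2952
歆斳	2.9963
垗慊愖	2.5641
暎曬呈	2.3993
噵敞	0.6055
唣崋	2.1918
摇嘠	2.7368
供梭	3.9939
吒扙昇	1.6016
擶岂	2.1694
擅	3.6835
啱哶湥	2.8050
櫿惘交	3.2042
栫毂嗦	3.7481
洄	2.7602
岳嘾淨	3.4979
橳	0.7242
奌弻	2.4463
扁	3.4052
孒	2.4580
棗	1.7513
洽斉毫	2.3948
恞囁洨	2.9912
橊	2.6019
幅溥垞	2.8446
徔崗澋	0.5966
公捱	1.5113
懨	2.8415
濠李毻	3.2688
朡	3.0484
来慬	2.6033
毝刻	2.6587
呢彛剹	2.9173
澿涊	1.5108
偳柊峘	2.1792
洔敋	3.7207
僕仆	2.6183
塺宋	4.3550
圍	1.3836
弛扔	2.6470
娃	2.8817
慕橓俾	2.7006
偉泒幐	3.4199
愢剩	2.2166
古拢涚	1.8224
倽	2.2584
潦娵彙	0.9650
嘊嬮椉	3.7033
減泹	3.0209
厎墯	1.9032
揬冾	2.7800
晻擖恐	3.6642
嵙湝抓	4.1199
沺搯	2.0791
暊撎朧	3.7952
冢	1.9908
儙校	2.2195
滧	3.6741
檓	3.2571
槢叻	1.0768
星惆	2.2251
悯岜净	2.5203
喠嶝	2.3411
晕叇	3.9944
槗濗栌	1.8432
汝	3.8744
滪曟宨	3.5028
掩宂桴	2.8764
壮慵朻	2.4405
涎姅巛	3.1201
伸戊枲	1.9672
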