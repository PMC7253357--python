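label,year,ancestry,cur_vv,cur_vm,cur_mm,nev_vv,nev_vm,nev_mm
Lang2007,2007,Caucasian,67,41,6,105,30,4
Wang2007,2007,Asian,30,51,20,12,20,16
Montag2008,2008,Caucasian,90,47,6,264,136,11
Landi2009,2009,Caucasian,879,521,62,458,277,41
Zhang2012,2012,Asian,81,177,64,74,156,76
Zhang2015,2015,Asian,215,456,173,114,253,107
JiangEA2017,2017,Caucasian,623,235,17,508,210,23
JiangAA2017,2017,African,1543,121,1,1636,100,3
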