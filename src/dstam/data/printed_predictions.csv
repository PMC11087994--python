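scenario,attribute,category,total,baseline,add_one,add_two
july,overall,all,2258823,1017011,1585437,1696205
november,overall,all,2258823,1574724,2063889,2194907
july,stratum_group,Low,1109549,221296,692535,708285
july,stratum_group,Middle,935699,645076,738967,787189
july,stratum_group,High,204589,147229,147714,194064
july,stratum_group,N.D.,8986,3410,6221,6667
november,stratum_group,Low,1109549,568115,1012179,1054841
november,stratum_group,Middle,935699,841224,883232,934581
november,stratum_group,High,204589,160082,160448,197011
november,stratum_group,N.D.,8986,5303,8030,8474
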