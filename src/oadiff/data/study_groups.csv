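group,id,age_class,sex,rank,n_observers,first_success_order,first_success_option,lift_order,pull_order,opportunistic
KB,Aare,adult,female,6,1,5,lift,7,,0
KB,Amur,adult,female,7,0,9,lift,9,,1
KB,Arn,juvenile,male,9,8,8,lift,4,5,0
KB,Avo,juvenile,male,5,9,2,lift,1,3,0
KB,Lif,adult,male,1,9,1,pull,5,1,0
KB,Mal,juvenile,male,8,5,7,pull,3,2,0
KB,Mis,juvenile,male,10,,,,,,0
KB,Nessi,adult,female,11,6,4,lift,6,6,0
KB,Yalu,adult,female,4,10,3,lift,2,4,0
KB,Yan,juvenile,male,3,5,6,lift,8,,0
KB,Yeni,adult,female,2,2,10,lift,10,,1
NH,Bela,juvenile,female,24,1,17,lift,16,,1
NH,Bos,juvenile,male,11,,,,,,0
NH,Can,adult,male,3,,,,,,0
NH,Gaya,adult,female,2,9,11,lift,11,10,0
NH,Gene,adult,female,1,25,1,lift,1,1,0
NH,Gla,juvenile,male,4,24,9,lift,8,,0
NH,Gran,juvenile,female,10,25,8,pull,9,6,0
NH,Jixi,juvenile,male,20,26,4,pull,4,2,0
NH,Lima,juvenile,female,22,3,13,lift,13,11,0
NH,Prai,juvenile,female,17,1,,,,,0
NH,Pret,adult,female,13,4,15,lift,19,,1
NH,Pro,juvenile,male,19,,,,,,0
NH,Pru,juvenile,male,16,8,14,lift,14,,1
NH,Renn,juvenile,female,25,5,18,lift,17,12,1
NH,Reva,adult,female,27,22,6,pull,6,4,0
NH,Rey,juvenile,male,28,,,,,,0
NH,Rhe,juvenile,male,7,25,5,pull,5,3,0
NH,Roma,adult,female,23,,,,,,0
NH,Rosl,juvenile,female,26,,,,,,0
NH,Tir,juvenile,male,14,3,16,lift,15,,1
NH,Twe,adult,male,6,,,,,,0
NH,Uji,juvenile,male,12,8,12,lift,12,,0
NH,Ula,juvenile,male,15,5,19,lift,18,,1
NH,Umt,juvenile,male,21,15,7,lift,7,9,0
NH,Upps,adult,female,5,14,2,lift,2,5,0
NH,Xala,juvenile,male,9,8,3,lift,3,8,0
NH,Xian,adult,female,8,24,10,lift,10,7,0
NH,Zan,juvenile,male,18,,,,,,0
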