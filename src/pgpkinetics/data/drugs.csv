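name,dG_sbd_aqueous_kcal_mol,partition_coefficient,Kd_nbd_M,pc_source,passive_rate_per_s
nilotinib,-11.1,25704,2e-9,drugbank,10
imatinib,-10.3,23988,2e-7,drugbank,10
dasatinib,-8.8,6606,2.5e-7,drugbank,10
paclitaxel,-10.9,3467,inf,drugbank,1
atp,,1,1.16e-5,n/a,1
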