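cruise,station,group,n_cells,cell_nfr_fmol_d,cell_nfr_sd,nifh_per_l,nifh_sd,community_nfr_nmol_l_d,community_nfr_sd,community_nfr_is_lod,printed_volumetric,printed_contribution_pct,printed_max_cell_nfr,printed_max_volumetric,printed_max_contribution_pct
SP1714,1,UCYN-A1,10,3.6,2.2,41000,730,2.3,1.3,False,0.15,6,14.4,0.6,26
SP1727,1,UCYN-A2,6,125.8,41.6,93000,4200,2.2,0.2,False,1.7,53,503.2,4.7,213
SP1727,5,UCYN-A1,6,12.8,13.5,62000,1500,0.8,0.1,True,0.8,99,51.2,3.2,397
SP1727,7,UCYN-A2,6,279.9,53.7,120000,2900,6.7,0.8,False,3.6,50,1119.6,13,201
SP1727,14,UCYN-A1,10,5.7,5.4,880000,81000,3.4,0.2,False,5.0,148,22.8,20.1,590
SP1727,14,UCYN-A2,5,27.0,15.4,29000,110,3.4,0.2,False,0.8,2,108,0.3,9
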