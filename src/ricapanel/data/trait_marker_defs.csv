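trait,gene,marker_id,chrom,pos_bp,negative_allele,positive_allele,mode,favorable_haplotypes,unfavorable_haplotypes,class_map,note
grain_size,GS3,chr03:16733441,chr03,16733441,G,T,single,T,G,,long grain favorable
blb_resistance,xa5,chr05:437499,chr05,437499,T,A,single,A,T,,resistant allele A
blb_resistance,Xa7,chr06:27275515,chr06,27275515,G,A,haplotype,AAC,GCA,,resistant haplotype AAC
blb_resistance,Xa7,chr06:27627615,chr06,27627615,C,A,haplotype,,,,
blb_resistance,Xa7,chr06:27761109,chr06,27761109,A,C,haplotype,,,,
blb_resistance,xa13,chr08:26448560,chr08,26448560,T,G,haplotype,GGC,TAT,,resistant haplotype GGC
blb_resistance,xa13,chr08:26709228,chr08,26709228,A,G,haplotype,,,,
blb_resistance,xa13,chr08:26898822,chr08,26898822,T,C,haplotype,,,,
blb_resistance,Xa4,chr11:27603799,chr11,27603799,C,A,single,A,C,,resistant allele A
blb_resistance,Xa21,chr11:21190115,chr11,21190115,C,T,single,T,C,,resistant allele T
blb_resistance,Xa23,chr11:22162729,chr11,22162729,C,T,haplotype,TTA,CCG,,resistant haplotype TTA
blb_resistance,Xa23,chr11:22453819,chr11,22453819,C,T,haplotype,,,,
blb_resistance,Xa23,chr11:23231455,chr11,23231455,G,A,haplotype,,,,
tungro_resistance,rstv1,chr07:22119347,chr07,22119347,A,G,single,G,A,,resistant allele G
submergence_tolerance,sub1,chr09:5922125,chr09,5922125,C,T,haplotype,TAG,CGC,,tolerant haplotype TAG
submergence_tolerance,sub1,chr09:6252407,chr09,6252407,G,A,haplotype,,,,
submergence_tolerance,sub1,chr09:6913547,chr09,6913547,C,G,haplotype,,,,
gelatinization_temp,ALK,chr06:6752756,chr06,6752756,A,G,single,G,A,,high-GT allele G
amylose_content,Wx,chr06:1765761,chr06,1765761,G,T,haplotype,,,"{""GAC"": ""high"", ""GAT"": ""high"", ""GCC"": ""intermediate"", ""TAC"": ""low"", ""TCC"": ""low""}",high-class spelled both GAC/GAC and GAC/GAT in source references; both GAC and GAT encoded as high
amylose_content,Wx,chr06:1768006,chr06,1768006,A,C,haplotype,,,,
amylose_content,Wx,chr06:1768998,chr06,1768998,C,T,haplotype,,,,
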