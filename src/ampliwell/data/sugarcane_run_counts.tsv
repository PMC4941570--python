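field	count
assembled	27220
demultiplexed	11750
non_demultiplexed	15345
over_length	125
chimeric	1444
nonspecific	16
usable_pre_filter	10290
wells_recovered_pre	377
usable_cov_ge10	7688
wells_recovered_cov	366
usable_reliable	9978
reliable_db_hits	9469
reliable_dataset_hits	509
error_prone	312
wells_recovered_reliable	375
n_plates	5
singleton_otus_low_coverage	335
singleton_otus_high_coverage	223
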