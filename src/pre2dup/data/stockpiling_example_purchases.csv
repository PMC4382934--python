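person_id,date,atc,vnr,n_packages,ddd_amount,dose_dispensing
P1,2005-01-01,N05AH02,141473,1,10,0
P1,2005-01-11,N05AH02,141473,1,10,0
P1,2005-01-16,N05AH02,141473,1,10,0
P1,2005-01-31,N05AH02,141473,1,10,0
P1,2005-02-10,N05AH02,141473,1,10,0
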