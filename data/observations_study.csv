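type,year_start,year_end,estimate,cv
abundance,2005,2005,6251.0,0.17
abundance,2008,2008,14264.0,0.084
abundance,2012,2012,20389.0,0.071
growth,1995,1998,0.074,0.446
growth,2002,2011,0.1135,0.115
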