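type,year_start,year_end,estimate,cv
abundance,2005,2005,13297.330744737177,0.17
abundance,2008,2008,12489.348406744262,0.084
abundance,2012,2012,16864.311239540373,0.071
growth,1995,1998,0.09967705068323587,0.3289165486976237
growth,2002,2011,0.058381326751355225,0.11481143381980564
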