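cohort,cases,images,included,excluded,slice_thickness_range_mm
ELCAP,50,50,46,4,1.25
LIDC,328,328,318,10,<=1.25
NEW,1888,4678,4672,6,2
WTC,1458,3795,3766,29,<=2
FAMRI,932,2137,2137,0,<=1.25
LC,2985,9820,9810,10,<=2
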