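cohort,cases,images,included,excluded,slice_thickness_range_mm
ELCAP,50,50,46,4,1.25
LIDC,328,328,318,10,<=1.25
NEW,1887,1892,1887,5,2
WTC,1458,3795,3767,28,<=2
FAMRI,710,1422,1422,0,<=1.25
LC,2169,6764,6752,12,<=2
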