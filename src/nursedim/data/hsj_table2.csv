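unit,date,minimal,intermediary,semi_intensive,intensive,unclassified
In. U 4th floor PRT/CNV,2016-09-07,21,10,3,0,0
In. U 4th floor PRT/CNV,2016-09-08,15,8,2,0,0
In. U 4th floor PRT/CNV,2016-09-09,16,8,2,0,0
In. U 4th floor PRT/CNV,2016-09-10,13,7,1,0,0
In. U 4th floor PRT/CNV,2016-09-11,15,6,2,0,0
In. U 4th floor PRT/CNV,2016-09-12,17,7,1,0,0
In. U 4th floor PRT/CNV,2016-09-13,24,8,2,0,0
In. U 4th floor PRT/CNV,2016-09-14,22,11,2,0,0
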