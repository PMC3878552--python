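review_id,study_unit_id,outcome_id,timepoint,arm_a_events,arm_a_total,arm_b_events,arm_b_total,status
BMJ,dorr_1986,dislocation,unspecified,7,39,2,50,reported
Cochrane,dorr_1986,dislocation,unspecified,7,39,2,50,reported
HTA,dorr_1986,dislocation,unspecified,7,39,2,50,reported
BMJ,skinner_ravikumar,dislocation,one_year,NR,NR,NR,NR,not_reported
Cochrane,skinner_ravikumar,dislocation,one_year,10,80,11,100,reported
HTA,skinner_ravikumar,dislocation,one_year,11,89,10,91,reported
BMJ,skinner_ravikumar,dislocation,thirteen_year,18,91,12,89,reported
Cochrane,skinner_ravikumar,dislocation,thirteen_year,NR,NR,NR,NR,not_reported
HTA,skinner_ravikumar,dislocation,thirteen_year,18,89,12,91,reported
BMJ,baker_2006,dislocation,unspecified,3,40,0,41,reported
Cochrane,baker_2006,dislocation,unspecified,3,40,0,41,reported
HTA,baker_2006,dislocation,unspecified,3,40,0,41,reported
BMJ,keating_2006,dislocation,unspecified,3,69,3,111,reported
Cochrane,keating_2006,dislocation,unspecified,3,69,2,69,reported
HTA,keating_2006,dislocation,unspecified,3,69,2,69,reported
BMJ,blomfeldt_2007,dislocation,unspecified,0,60,0,60,reported
Cochrane,blomfeldt_2007,dislocation,unspecified,0,60,0,60,reported
HTA,blomfeldt_2007,dislocation,unspecified,0,60,0,60,reported
BMJ,macaulay_2008,dislocation,unspecified,1,17,0,23,reported
Cochrane,macaulay_2008,dislocation,unspecified,1,17,0,23,reported
HTA,macaulay_2008,dislocation,unspecified,1,17,0,23,reported
BMJ,mouzopoulos_2008,dislocation,unspecified,NR,NR,NR,NR,not_reported
Cochrane,mouzopoulos_2008,dislocation,unspecified,NR,NR,NR,NR,not_reported
HTA,mouzopoulos_2008,dislocation,unspecified,NR,NR,NR,NR,not_reported
BMJ,dorr_1986,mortality_1y,unspecified,3,39,4,50,reported
Cochrane,dorr_1986,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
HTA,dorr_1986,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
BMJ,skinner_ravikumar,mortality_1y,unspecified,21,91,24,89,reported
Cochrane,skinner_ravikumar,mortality_1y,unspecified,18,80,27,100,reported
HTA,skinner_ravikumar,mortality_1y,unspecified,20,89,25,91,reported
BMJ,baker_2006,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
Cochrane,baker_2006,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
HTA,baker_2006,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
BMJ,keating_2006,mortality_1y,unspecified,4,69,11,111,reported
Cochrane,keating_2006,mortality_1y,unspecified,4,69,6,69,reported
HTA,keating_2006,mortality_1y,unspecified,4,69,6,69,reported
BMJ,blomfeldt_2007,mortality_1y,unspecified,4,60,3,60,reported
Cochrane,blomfeldt_2007,mortality_1y,unspecified,4,60,3,60,reported
HTA,blomfeldt_2007,mortality_1y,unspecified,4,60,3,60,reported
BMJ,macaulay_2008,mortality_1y,unspecified,1,17,5,23,reported
Cochrane,macaulay_2008,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
HTA,macaulay_2008,mortality_1y,unspecified,NR,NR,NR,NR,not_reported
BMJ,mouzopoulos_2008,mortality_1y,unspecified,10,43,13,43,reported
Cochrane,mouzopoulos_2008,mortality_1y,unspecified,6,43,6,43,reported
HTA,mouzopoulos_2008,mortality_1y,unspecified,6,39,6,38,reported
BMJ,dorr_1986,revision,unspecified,2,39,4,50,reported
Cochrane,dorr_1986,revision,unspecified,2,39,4,50,reported
HTA,dorr_1986,revision,unspecified,2,39,4,50,reported
BMJ,skinner_ravikumar,revision,one_year,NR,NR,NR,NR,not_reported
Cochrane,skinner_ravikumar,revision,one_year,3,80,13,100,reported
HTA,skinner_ravikumar,revision,one_year,4,89,12,91,reported
BMJ,skinner_ravikumar,revision,thirteen_year,6,91,22,89,reported
Cochrane,skinner_ravikumar,revision,thirteen_year,NR,NR,NR,NR,not_reported
HTA,skinner_ravikumar,revision,thirteen_year,6,89,22,91,reported
BMJ,baker_2006,revision,unspecified,1,40,6,41,reported
Cochrane,baker_2006,revision,unspecified,1,40,3,41,reported
HTA,baker_2006,revision,unspecified,1,40,6,41,reported
BMJ,keating_2006,revision,unspecified,NR,NR,NR,NR,not_reported
Cochrane,keating_2006,revision,unspecified,NR,NR,NR,NR,not_reported
HTA,keating_2006,revision,unspecified,NR,NR,NR,NR,not_reported
BMJ,blomfeldt_2007,revision,unspecified,4,60,3,60,reported
Cochrane,blomfeldt_2007,revision,unspecified,1,60,0,60,reported
HTA,blomfeldt_2007,revision,unspecified,0,60,0,60,reported
BMJ,macaulay_2008,revision,unspecified,1,17,0,23,reported
Cochrane,macaulay_2008,revision,unspecified,1,17,0,23,reported
HTA,macaulay_2008,revision,unspecified,1,17,0,23,reported
BMJ,mouzopoulos_2008,revision,unspecified,1,43,3,43,reported
Cochrane,mouzopoulos_2008,revision,unspecified,1,43,5,43,reported
HTA,mouzopoulos_2008,revision,unspecified,1,39,5,38,reported
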