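review_id,study_unit_id,outcome_id,variable,label,rationale
BMJ,skinner_ravikumar,dislocation,arm_a_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,dislocation,arm_b_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,dislocation,arm_a_events,selection,13-year follow-up publication analysed in place of the 1-year data; numerators recalculated from reported percentages
BMJ,skinner_ravikumar,dislocation,arm_b_events,selection,13-year follow-up publication analysed in place of the 1-year data; numerators recalculated from reported percentages
BMJ,keating_2006,dislocation,arm_b_events,selection,Comparator events taken from a separate trial arm run under different eligibility criteria
BMJ,keating_2006,dislocation,arm_b_total,selection,Comparator denominator (111) from a separate trial arm run under different eligibility criteria
Cochrane,skinner_ravikumar,dislocation,arm_a_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,dislocation,arm_b_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,dislocation,arm_a_events,selection,Numerators recalculated from reported percentages on the review's own denominators
Cochrane,skinner_ravikumar,dislocation,arm_b_events,selection,Numerators recalculated from reported percentages on the review's own denominators
BMJ,dorr_1986,mortality_1y,arm_a_events,error,Primary study reports 7 deaths across both arms; split of 3 and 4 per arm has no source
BMJ,dorr_1986,mortality_1y,arm_b_events,error,Primary study reports 7 deaths across both arms; split of 3 and 4 per arm has no source
BMJ,dorr_1986,mortality_1y,arm_a_total,identical,Denominator matches the primary publication (reference did not report this outcome)
BMJ,dorr_1986,mortality_1y,arm_b_total,identical,Denominator matches the primary publication (reference did not report this outcome)
BMJ,skinner_ravikumar,mortality_1y,arm_a_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,mortality_1y,arm_b_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,mortality_1y,arm_a_events,selection,Numerators recalculated from reported percentages on transposed denominators
BMJ,skinner_ravikumar,mortality_1y,arm_b_events,selection,Numerators recalculated from reported percentages on transposed denominators
BMJ,keating_2006,mortality_1y,arm_b_events,selection,Comparator events taken from a separate trial arm run under different eligibility criteria
BMJ,keating_2006,mortality_1y,arm_b_total,selection,Comparator denominator (111) from a separate trial arm run under different eligibility criteria
BMJ,macaulay_2008,mortality_1y,arm_a_events,selection,Reported 6-month deaths analysed as 1-year data
BMJ,macaulay_2008,mortality_1y,arm_b_events,selection,Reported 6-month deaths analysed as 1-year data
BMJ,macaulay_2008,mortality_1y,arm_a_total,identical,Denominator matches the primary publication (reference omitted the study from the 1-year analysis)
BMJ,macaulay_2008,mortality_1y,arm_b_total,identical,Denominator matches the primary publication (reference omitted the study from the 1-year analysis)
BMJ,mouzopoulos_2008,mortality_1y,arm_a_events,selection,Revisions and post-randomisation exclusions counted as deaths
BMJ,mouzopoulos_2008,mortality_1y,arm_b_events,selection,Revisions and post-randomisation exclusions counted as deaths
BMJ,mouzopoulos_2008,mortality_1y,arm_a_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
BMJ,mouzopoulos_2008,mortality_1y,arm_b_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
Cochrane,skinner_ravikumar,mortality_1y,arm_a_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,mortality_1y,arm_b_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,mortality_1y,arm_a_events,selection,Numerators recalculated from reported percentages on the review's own denominators
Cochrane,skinner_ravikumar,mortality_1y,arm_b_events,selection,Numerators recalculated from reported percentages on the review's own denominators
Cochrane,mouzopoulos_2008,mortality_1y,arm_a_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
Cochrane,mouzopoulos_2008,mortality_1y,arm_b_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
BMJ,skinner_ravikumar,revision,arm_a_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,revision,arm_b_total,error,Denominators for the two groups transposed when entering data
BMJ,skinner_ravikumar,revision,arm_b_events,error,25% used instead of the reported 24% when recalculating the numerator
BMJ,skinner_ravikumar,revision,arm_a_events,selection,13-year follow-up publication analysed in place of the 1-year data
BMJ,blomfeldt_2007,revision,arm_a_events,selection,Re-operations on the contra-lateral side and for lower-limb trauma counted as revisions
BMJ,blomfeldt_2007,revision,arm_b_events,selection,Re-operations on the contra-lateral side and for lower-limb trauma counted as revisions
BMJ,mouzopoulos_2008,revision,arm_b_events,selection,Two comparator revisions excluded from the analysis despite the outcome occurring
BMJ,mouzopoulos_2008,revision,arm_a_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
BMJ,mouzopoulos_2008,revision,arm_b_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
Cochrane,skinner_ravikumar,revision,arm_a_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,revision,arm_b_total,error,Review generated its own denominators after missing the follow-up publication that reports arm sizes
Cochrane,skinner_ravikumar,revision,arm_a_events,selection,Numerators recalculated from reported percentages on the review's own denominators
Cochrane,skinner_ravikumar,revision,arm_b_events,selection,Numerators recalculated from reported percentages on the review's own denominators
Cochrane,baker_2006,revision,arm_b_events,selection,Planned or awaited revisions omitted; only completed revisions counted
Cochrane,blomfeldt_2007,revision,arm_a_events,selection,A wound revision counted as a revision; reference counts implant revisions only
Cochrane,mouzopoulos_2008,revision,arm_a_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
Cochrane,mouzopoulos_2008,revision,arm_b_total,selection,All randomised participants retained; reference applied the trial's post-randomisation exclusions
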