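unit_id,member_publications,notes
dorr_1986,Dorr 1986,
skinner_ravikumar,Skinner 1989;Ravikumar 2000,Ravikumar 2000 is the 13-year follow-up publication of the Skinner cohort; only Ravikumar reports arm denominators
baker_2006,Baker 2006,
keating_2006,Keating 2006,A third non-randomised arm of 111 participants existed under different eligibility criteria
blomfeldt_2007,Blomfeldt 2007,
macaulay_2008,Macaulay 2008,1-year mortality not reported; 6-month and up-to-2-year deaths reported
mouzopoulos_2008,Mouzopoulos 2008,Reference applied the trial's post-randomisation exclusions (ITT denominators differ)
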