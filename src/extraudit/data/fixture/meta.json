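{
 "reviews": ["BMJ", "Cochrane", "HTA"],
 "reference_review_id": "HTA",
 "analysis_exclusions": [
  {
   "review_id": "Cochrane",
   "study_unit_id": "blomfeldt_2007",
   "outcome_id": "revision",
   "reason": "The single extracted event was a wound revision, not an implant revision; the pooled revision analysis for this review omitted the study"
  }
 ]
}
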