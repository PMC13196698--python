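{
 "attributes": [
  {
   "delimiter": ";",
   "name": "sex",
   "structure": "single",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "ancestry",
   "structure": "multi",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "disease",
   "structure": "single",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "treatment",
   "structure": "multi",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "sample_type",
   "structure": "single",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "age",
   "structure": "numeric",
   "subfields": null
  },
  {
   "delimiter": ";",
   "name": "biomarker",
   "structure": "composite",
   "subfields": [
    "CRP",
    "IL6",
    "TNF"
   ]
  }
 ]
}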