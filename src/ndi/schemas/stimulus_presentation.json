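{
 "fields": {
  "presentations": {
   "kind": "list",
   "required": true
  },
  "triggers": {
   "kind": "list",
   "required": false
  }
 },
 "name": "stimulus_presentation",
 "superclasses": [
  "ndi_document",
  "ndi_epochid"
 ],
 "version": 1
}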