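{
 "fields": {
  "directions": {
   "kind": "list",
   "required": true
  },
  "mean": {
   "kind": "list",
   "required": true
  },
  "n": {
   "kind": "list",
   "required": true
  },
  "sem": {
   "kind": "list",
   "required": true
  }
 },
 "name": "tuning_curve",
 "superclasses": [
  "ndi_document"
 ],
 "version": 1
}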