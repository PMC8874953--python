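{
 "fields": {
  "clocktypes": {
   "kind": "list",
   "required": true
  },
  "kind": {
   "kind": "string",
   "required": true
  },
  "sample_rate": {
   "kind": "number",
   "required": false
  },
  "t0": {
   "kind": "number",
   "required": true
  },
  "t1": {
   "kind": "number",
   "required": true
  }
 },
 "name": "epoch",
 "superclasses": [
  "ndi_document",
  "ndi_epochid"
 ],
 "version": 1
}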