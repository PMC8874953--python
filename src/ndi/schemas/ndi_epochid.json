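{
 "fields": {
  "epoch_id": {
   "kind": "string",
   "required": true
  }
 },
 "name": "ndi_epochid",
 "superclasses": [],
 "version": 1
}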