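{
 "fields": {
  "app": {
   "kind": "object",
   "required": true
  }
 },
 "name": "ndi_app",
 "superclasses": [],
 "version": 1
}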