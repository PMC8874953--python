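{
 "fields": {
  "di": {
   "kind": "number",
   "required": true
  },
  "fit": {
   "kind": "object",
   "required": true
  },
  "fit_residual": {
   "kind": "number",
   "required": false
  },
  "oi": {
   "kind": "number",
   "required": true
  }
 },
 "name": "oridir_tuning",
 "superclasses": [
  "ndi_document",
  "ndi_app"
 ],
 "version": 1
}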